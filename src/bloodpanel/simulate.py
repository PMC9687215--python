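"""Synthetic whole-blood expression datasets with planted disease signal.

The generator emulates the structure of normalized log2 microarray matrices:
per-probe baselines drawn uniformly from a plausible log2 intensity range,
Gaussian probe-level noise, a near-constant reference transcript (GUSB-like),
a small planted set of disease-discriminative probes receiving an additive
log2 effect, optional duplicate probes per gene, optional two-batch shifts,
and partially overlapping probe sets across two simulated platforms.

Everything is a pure function of the seed, so downstream selection and
validation stages can be tested for parameter recovery without any external
download.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import (
    CONTROL,
    DISEASE,
    ExpressionDataset,
    ProbeAnnotation,
    write_expression_matrix,
    write_labels,
)

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "generate_dataset",
    "generate_probe_annotation",
    "split_platforms",
    "write_fixture",
]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic expression generator (all on the log2 scale)."""

    n_control: int = 100
    n_disease: int = 100
    n_probes: int = 2000
    n_informative: int = 15
    effect_size: float = 1.5
    baseline_mean_range: tuple[float, float] = (6.0, 14.0)
    noise_sd: float = 1.0
    reference_probe_id: str = "GUSB"
    reference_sd: float = 0.05
    duplicate_gene_fraction: float = 0.0
    batch_shift: float | None = None
    heteroscedastic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control", "n_disease", "n_probes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if not 0 <= self.n_informative <= self.n_probes - 1:
            raise ValueError("need 0 <= n_informative <= n_probes - 1 (one probe is the reference)")
        if self.noise_sd <= 0 or self.reference_sd <= 0:
            raise ValueError("noise_sd and reference_sd must be > 0")
        if not 0 <= self.duplicate_gene_fraction <= 1:
            raise ValueError("duplicate_gene_fraction must be in [0, 1]")
        lo, hi = self.baseline_mean_range
        if not lo < hi:
            raise ValueError("baseline_mean_range must be an increasing pair")


@dataclass(frozen=True)
class GroundTruth:
    """Which probes carry planted signal, and each sample's class."""

    informative_probe_ids: frozenset[str]
    labels: dict[str, str]


def _probe_ids(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(1, n + 1)]


def generate_dataset(params: SimulationParams) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one labeled probes x samples dataset under ``params``.

    Each probe g gets a baseline mu_g ~ Uniform(baseline_mean_range) and
    entries Normal(mu_g, noise_sd); informative probes additionally receive
    +effect_size in disease samples. The reference probe is
    Normal(mid-range, reference_sd) in every sample and is never
    informative. With ``batch_shift`` set, the second half of the samples
    of each class is offset by that amount (a balanced two-batch design).
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n_samples = p.n_control + p.n_disease

    probe_ids = _probe_ids(p.n_probes - 1)
    # reference replaces the final slot so IDs stay contiguous
    probe_ids.append(p.reference_probe_id)
    if len(set(probe_ids)) != p.n_probes:
        raise ValueError(f"reference_probe_id {p.reference_probe_id!r} collides with a generated probe ID")

    baselines = rng.uniform(*p.baseline_mean_range, size=p.n_probes)
    if p.heteroscedastic:
        sds = rng.uniform(0.1, 1.0, size=p.n_probes)
    else:
        sds = np.full(p.n_probes, p.noise_sd)

    informative_idx = rng.choice(p.n_probes - 1, size=p.n_informative, replace=False)

    values = rng.normal(baselines[:, None], sds[:, None], size=(p.n_probes, n_samples))
    y = np.r_[np.zeros(p.n_control, dtype=int), np.ones(p.n_disease, dtype=int)]
    values[np.ix_(informative_idx, np.flatnonzero(y == 1))] += p.effect_size

    mu_ref = float(np.mean(p.baseline_mean_range))
    values[-1, :] = rng.normal(mu_ref, p.reference_sd, size=n_samples)

    if p.batch_shift is not None:
        batch = np.zeros(n_samples, dtype=bool)
        batch[p.n_control // 2 : p.n_control] = True
        batch[p.n_control + p.n_disease // 2 :] = True
        values[:, batch] += p.batch_shift

    sample_ids = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    labels = pd.Series(
        [CONTROL if c == 0 else DISEASE for c in y], index=sample_ids, name="label"
    )
    dataset = ExpressionDataset(
        values=pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        labels=labels,
        platform="simulated",
    )
    truth = GroundTruth(
        informative_probe_ids=frozenset(probe_ids[i] for i in informative_idx),
        labels=dict(labels),
    )
    return dataset, truth


def generate_probe_annotation(
    n_genes: int, duplicate_gene_fraction: float, seed: int
) -> ProbeAnnotation:
    """Probe -> (gene symbol, EntrezID) table with a controlled duplicate rate.

    A ``duplicate_gene_fraction`` of genes (rounded) receive exactly two
    probes, emulating multi-probe genes that must be averaged when
    collapsing to EntrezIDs. Probe IDs follow the generator's ``P#####``
    scheme so the table aligns with a generated dataset of matching size.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    if not 0 <= duplicate_gene_fraction <= 1:
        raise ValueError("duplicate_gene_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_dup = int(np.floor(duplicate_gene_fraction * n_genes + 0.5))
    duplicated = set(rng.choice(n_genes, size=n_dup, replace=False).tolist())

    rows = []
    probe_counter = 1
    for g in range(n_genes):
        copies = 2 if g in duplicated else 1
        for _ in range(copies):
            rows.append(
                {
                    "probe_id": f"P{probe_counter:05d}",
                    "gene_symbol": f"GENE{g + 1}",
                    "entrez_id": str(100000 + g + 1),
                }
            )
            probe_counter += 1
    return ProbeAnnotation(pd.DataFrame(rows))


def split_platforms(
    dataset: ExpressionDataset, overlap_fraction: float, seed: int
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Split one dataset into two simulated platforms with partial probe overlap.

    Both outputs cover the same samples. Exactly
    round(overlap_fraction x n_probes) probes are shared (values copied
    unchanged, never re-noised); the remaining probes are divided
    disjointly between the two outputs.
    """
    if not 0 < overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in (0, 1]")
    n = dataset.n_probes
    n_shared = int(np.floor(overlap_fraction * n + 0.5))
    if n_shared == 0:
        raise ValueError("overlap would contain no probes; nothing is matchable")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shared = order[:n_shared]
    rest = order[n_shared:]
    only_a, only_b = rest[: len(rest) // 2], rest[len(rest) // 2 :]

    ids = dataset.probe_ids
    a_ids = sorted(ids[np.sort(np.r_[shared, only_a].astype(int))])
    b_ids = sorted(ids[np.sort(np.r_[shared, only_b].astype(int))])
    a = dataclasses.replace(dataset.subset_probes(a_ids), platform=f"{dataset.platform}_A")
    b = dataclasses.replace(dataset.subset_probes(b_ids), platform=f"{dataset.platform}_B")
    return a, b


def write_fixture(
    dataset: ExpressionDataset,
    truth: GroundTruth,
    outdir,
    params: SimulationParams | None = None,
    annotation: ProbeAnnotation | None = None,
) -> dict[str, Path]:
    """Write a dataset as plain-text fixture files (TSV + ground-truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "expression.tsv",
        "labels": outdir / "labels.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_expression_matrix(dataset, paths["matrix"])
    write_labels(dataset, paths["labels"])
    if annotation is not None:
        paths["annotation"] = outdir / "annotation.tsv"
        annotation.write(paths["annotation"])
    payload = {
        "informative_probe_ids": sorted(truth.informative_probe_ids),
        "labels": truth.labels,
        "params": dataclasses.asdict(params) if params is not None else None,
    }
    paths["ground_truth"].write_text(json.dumps(payload, indent=2, sort_keys=True))
    return paths
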