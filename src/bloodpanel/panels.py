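"""Transcript panels: the ordered feature lists fed to the discriminant.

A panel is an ordered list of entries (rank, feature_id, optional gene
symbol). The package ships the published panels it validates against:

* the 22 literature-curated transcripts in three functional groups
  (inflammation, epigenetics, stress), and
* the nine disease-specific 20-transcript panels produced by the
  random-forest selection protocol (AD1, AD2, PD1, PD2, HD, ALS1, ALS2,
  bvFTD, FRDA), transcribed from the published tables.

Microarray annotations sometimes print composite identifiers such as
``PITHD1/C1orf128``; symbol comparisons therefore match case-insensitively
on any slash-separated alias.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "PanelEntry",
    "Panel",
    "symbol_aliases",
    "read_panel",
    "write_panel",
    "load_builtin_panel",
    "builtin_panel_names",
]

_DATA_PACKAGE = "bloodpanel.panels_data"

BUILTIN_PANELS = (
    "inflammation",
    "epigenetics",
    "stress",
    "combined22",
    "AD1",
    "AD2",
    "PD1",
    "PD2",
    "HD",
    "ALS1",
    "ALS2",
    "bvFTD",
    "FRDA",
)


def symbol_aliases(symbol: str | None) -> set[str]:
    """Case-folded aliases of a gene identifier (slash composites split)."""
    if not symbol:
        return set()
    return {part.strip().lower() for part in str(symbol).split("/") if part.strip()}


@dataclass(frozen=True)
class PanelEntry:
    rank: int
    feature_id: str
    gene_symbol: str | None = None


@dataclass
class Panel:
    """Ordered transcript panel with optional provenance name."""

    entries: list[PanelEntry]
    name: str = ""

    @property
    def feature_ids(self) -> list[str]:
        return [e.feature_id for e in self.entries]

    @property
    def gene_symbols(self) -> list[str]:
        return [e.gene_symbol or e.feature_id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_ids(cls, ids, name: str = "") -> "Panel":
        return cls(
            entries=[PanelEntry(rank=i + 1, feature_id=str(f)) for i, f in enumerate(ids)],
            name=name,
        )


def read_panel(path, name: str | None = None) -> Panel:
    """Read a two-column (rank, feature_id [, gene_symbol]) TSV panel."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"rank", "feature_id"} <= set(table.columns):
        raise ValueError(f"{path.name}: panel files need columns rank, feature_id")
    has_symbol = "gene_symbol" in table.columns
    entries = [
        PanelEntry(
            rank=int(row["rank"]),
            feature_id=row["feature_id"],
            gene_symbol=(row["gene_symbol"] if has_symbol and pd.notna(row["gene_symbol"]) else None),
        )
        for _, row in table.iterrows()
    ]
    return Panel(entries=entries, name=name if name is not None else path.stem)


def write_panel(panel: Panel, path) -> None:
    pd.DataFrame(
        {
            "rank": [e.rank for e in panel.entries],
            "feature_id": [e.feature_id for e in panel.entries],
            "gene_symbol": [e.gene_symbol or e.feature_id for e in panel.entries],
        }
    ).to_csv(path, sep="\t", index=False)


def builtin_panel_names() -> tuple[str, ...]:
    return BUILTIN_PANELS


def load_builtin_panel(name: str) -> Panel:
    """Load one of the published panels shipped with the package."""
    if name not in BUILTIN_PANELS:
        raise KeyError(f"unknown panel {name!r}; available: {BUILTIN_PANELS}")
    ref = resources.files(_DATA_PACKAGE) / f"{name}.tsv"
    with resources.as_file(ref) as path:
        return read_panel(path, name=name)
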