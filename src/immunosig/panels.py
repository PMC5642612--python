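"""Immune gene panels and their registry.

A :class:`GenePanel` is a named, ordered set of HGNC-style gene symbols.
Symbols are trimmed and upper-cased on entry; duplicates (after
case-normalisation) are collapsed and counted.  No alias resolution is
performed: a symbol absent from a cohort is reported, never remapped.

The package ships four panels: the 722-gene NanoString-like immune
profiling panel, and synthetic stand-ins for the type-I interferon
(97 genes), type-II interferon (200 genes) and T-cell cytotoxicity
(115 genes) pathway sets.  Their union is the 924-gene combined immune
panel used by the ranking stage.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

_PACKAGED_PANELS = {
    "nanostring": "nanostring_panel.txt",
    "ifn_alpha": "ifn_alpha_synthetic.txt",
    "ifn_gamma": "ifn_gamma_synthetic.txt",
    "cytotoxic": "cytotoxic_synthetic.txt",
}


class PanelError(ValueError):
    """Raised for malformed or empty panel inputs."""


def _normalize_symbol(raw: str, *, path: str = "<memory>", lineno: int = 0) -> str:
    sym = raw.strip().upper()
    if not sym:
        raise PanelError(f"{path}:{lineno}: empty or whitespace-only gene symbol")
    if any(ch.isspace() for ch in sym):
        raise PanelError(f"{path}:{lineno}: unparseable symbol {raw!r} (internal whitespace)")
    return sym


@dataclass(frozen=True)
class GenePanel:
    """A named set of gene symbols with provenance.

    ``genes`` preserves first-seen order; membership tests are
    case-insensitive because symbols are stored upper-case.
    """

    name: str
    genes: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise PanelError(f"panel {self.name!r} is empty")
        seen = set()
        for g in self.genes:
            if not g or g != g.strip().upper() or any(c.isspace() for c in g):
                raise PanelError(f"panel {self.name!r}: invalid symbol {g!r}")
            if g in seen:
                raise PanelError(f"panel {self.name!r}: duplicate symbol {g!r}")
            seen.add(g)
        object.__setattr__(self, "_members", frozenset(seen))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol.strip().upper() in self._members  # type: ignore[attr-defined]

    def __iter__(self):
        return iter(self.genes)

    @classmethod
    def from_symbols(cls, name: str, symbols: Iterable[str], source: str = "") -> "GenePanel":
        """Build a panel, collapsing case-duplicates (logged)."""
        ordered: list[str] = []
        seen: set[str] = set()
        dupes = 0
        for i, raw in enumerate(symbols, start=1):
            sym = _normalize_symbol(str(raw), lineno=i)
            if sym in seen:
                dupes += 1
                continue
            seen.add(sym)
            ordered.append(sym)
        if dupes:
            logger.info("panel %s: collapsed %d duplicate symbol(s)", name, dupes)
        return cls(name=name, genes=tuple(ordered), source=source)


def load_panel(path: str | Path, name: str | None = None) -> GenePanel:
    """Load a gene panel from a plain list or two-column CSV.

    Accepted layouts: one symbol per line, or ``symbol,panel-tag`` CSV
    rows.  Lines starting with ``#`` and blank lines are ignored.
    Duplicate symbols (case-insensitive) are collapsed and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    symbols: list[str] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].lstrip().startswith("#"):
                continue
            if len(row) > 2:
                raise PanelError(f"{path}:{lineno}: expected 1 or 2 columns, got {len(row)}")
            symbols.append(_normalize_symbol(row[0], path=str(path), lineno=lineno))
    if not symbols:
        raise PanelError(f"{path}: no gene symbols found")
    ordered, seen, dupes = [], set(), 0
    for s in symbols:
        if s in seen:
            dupes += 1
        else:
            seen.add(s)
            ordered.append(s)
    if dupes:
        logger.info("panel %s (%s): collapsed %d duplicate symbol(s)", name or path.stem, path, dupes)
    return GenePanel(name=name or path.stem, genes=tuple(ordered), source=str(path))


def union_panels(panels: list[GenePanel], name: str = "combined") -> GenePanel:
    """Set union of panels with stable sorted ordering.

    Provenance (``source``) records, per gene, which member panels
    contributed it; retrieve the full mapping with
    :func:`membership_table`.
    """
    if not panels:
        raise PanelError("union_panels requires at least one panel")
    members = sorted({g for p in panels for g in p.genes})
    source = "union(" + ", ".join(p.name for p in panels) + ")"
    return GenePanel(name=name, genes=tuple(members), source=source)


def membership_table(panels: list[GenePanel]) -> dict[str, tuple[str, ...]]:
    """Map each gene in the union to the names of the panels containing it."""
    table: dict[str, list[str]] = {}
    for p in panels:
        for g in p.genes:
            table.setdefault(g, []).append(p.name)
    return {g: tuple(v) for g, v in sorted(table.items())}


@dataclass
class PanelRegistry:
    """Holds named panels plus their combined union panel."""

    panels: dict[str, GenePanel] = field(default_factory=dict)

    def add(self, panel: GenePanel) -> None:
        if panel.name in self.panels:
            raise PanelError(f"panel {panel.name!r} already registered")
        self.panels[panel.name] = panel

    @property
    def combined(self) -> GenePanel:
        return union_panels(list(self.panels.values()))

    def __getitem__(self, name: str) -> GenePanel:
        return self.panels[name]

    def __len__(self) -> int:
        return len(self.panels)


def _packaged_path(filename: str) -> Path:
    return Path(resources.files("immunosig.data") / filename)


def load_packaged_panel(key: str) -> GenePanel:
    """Load one of the packaged panels by key.

    Keys: ``nanostring`` (the 722-gene immune profiling list),
    ``ifn_alpha``, ``ifn_gamma``, ``cytotoxic`` (synthetic stand-ins of
    the documented sizes 97/200/115).
    """
    try:
        fn = _PACKAGED_PANELS[key]
    except KeyError:
        raise KeyError(f"unknown packaged panel {key!r}; choose from {sorted(_PACKAGED_PANELS)}")
    return load_panel(_packaged_path(fn), name=key)


def default_registry() -> PanelRegistry:
    """Registry of the four packaged immune panels (combined union: 924 genes)."""
    reg = PanelRegistry()
    for key in _PACKAGED_PANELS:
        reg.add(load_packaged_panel(key))
    return reg
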