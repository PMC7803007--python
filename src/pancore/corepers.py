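"""Core and persistent genome classification.

With G genomes and a genome-fraction threshold ``tol`` (T = tol * G), a
family whose members occur exactly once in ``n_one`` genomes, more than once
in ``n_multi`` genomes and not at all in ``n_zero`` genomes is

* **core**   iff n_one = G (single copy in every genome; tol is ignored),
* **strict** iff n_one >= T and n_multi = 0,
* **mixed**  iff n_one >= T (other genomes may lack it or have several copies),
* **multi**  iff n_one + n_multi >= T (at least one member in T genomes).

Comparisons use >=, so a family sitting exactly on the threshold is kept
("at least N%").  At equal tol the selections nest:
core <= strict <= mixed <= multi.

Strict mode rejects families with *any* multi-copy genome — the reading that
makes the nesting chain hold; it is the one this package commits to.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .pangenome import PangenomeMatrix, read_pangenome_lst

MODES = ("core", "strict", "mixed", "multi")


@dataclass
class PersistenceResult:
    mode: str
    tol: float
    selected: list[int]
    per_family_status: dict[int, tuple[int, int, int]]  # (n_one, n_multi, n_zero)


def family_status(m: PangenomeMatrix) -> dict[int, tuple[int, int, int]]:
    """(n_exactly_one, n_multi, n_zero) genome counts for every family."""
    counts = m.counts
    n_one = (counts == 1).sum(axis=1)
    n_multi = (counts >= 2).sum(axis=1)
    n_zero = (counts == 0).sum(axis=1)
    return {
        int(fid): (int(n_one[fid]), int(n_multi[fid]), int(n_zero[fid]))
        for fid in counts.index
    }


def classify(m: PangenomeMatrix, tol: float = 1.0, mode: str = "strict") -> PersistenceResult:
    """Select the families that satisfy ``mode`` at threshold ``tol``."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if not 0 < tol <= 1:
        raise ValueError(f"tol must be in (0, 1], got {tol}")
    if mode == "core":
        tol = 1.0
    G = len(m.genomes)
    T = tol * G
    status = family_status(m)
    selected = []
    for fid, (n_one, n_multi, _n_zero) in status.items():
        if mode == "core":
            keep = n_one == G
        elif mode == "strict":
            keep = n_one >= T and n_multi == 0
        elif mode == "mixed":
            keep = n_one >= T
        else:  # multi
            keep = (n_one + n_multi) >= T
        if keep:
            selected.append(fid)
    return PersistenceResult(mode=mode, tol=tol, selected=sorted(selected),
                             per_family_status=status)


def write_persistent(r: PersistenceResult, m: PangenomeMatrix, out: str | Path) -> Path:
    """Write the selected families in the pangenome membership-list format."""
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    with out.open("w") as fh:
        fh.write(f"# persistent genome: mode={r.mode} tol={r.tol:g} "
                 f"families={len(r.selected)}\n")
        for fid in r.selected:
            fh.write(" ".join([str(fid), *sorted(m.families[fid])]) + "\n")
    return out


def read_persistent(path: str | Path) -> PangenomeMatrix:
    """Read a persistent-genome membership file back (align-module input)."""
    return read_pangenome_lst(path)
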