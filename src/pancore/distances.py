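"""Symmetric genome distance matrices shared by the sketching and tree stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class DistanceMatrix:
    """A symmetric, zero-diagonal matrix of pairwise genome distances in [0, 1].

    ``ids`` fixes the row/column order; ``values`` is a dense float array.
    """

    ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"distance matrix shape {self.values.shape} does not match {n} ids"
            )
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def lookup(self) -> dict[frozenset, float]:
        """Pairwise lookup keyed by unordered genome-id pairs."""
        out: dict[frozenset, float] = {}
        for i, a in enumerate(self.ids):
            for j in range(i + 1, len(self.ids)):
                out[frozenset((a, self.ids[j]))] = float(self.values[i, j])
        return out

    def write_tsv(self, path: str | Path) -> None:
        """Square phylip-style TSV: a count line then one row per genome."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for gid, row in zip(self.ids, self.values):
                fh.write(gid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DistanceMatrix":
        lines = Path(path).read_text().splitlines()
        n = int(lines[0].strip())
        ids, rows = [], []
        for line in lines[1 : n + 1]:
            parts = line.split("\t")
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1 : n + 1]])
        return cls(ids=ids, values=np.array(rows))
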