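"""Tabular omics data container.

A :class:`DataSeries` is a numeric matrix whose rows are keyed by identifier
*sets* (a measurement may carry several database accessions) and whose
columns are named samples, optionally partitioned into named groups to
express replicate or time-point structure.  Missing values are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError


@dataclass
class DataSeries:
    name: str
    row_ids: list[frozenset[str]]
    samples: list[str]
    matrix: np.ndarray  # shape (n_rows, n_samples), NaN = missing
    groups: dict[str, list[str]] = field(default_factory=dict)
    annotations: dict[str, str] = field(default_factory=dict)
    duplicate_rows: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.row_ids), len(self.samples)):
            raise ConfigError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.samples)} samples"
            )
        if self.groups:
            flat = [s for g in self.groups.values() for s in g]
            if sorted(flat) != sorted(self.samples):
                raise ConfigError("sample groups must partition the samples exactly")
        for s in self.samples:
            if self.samples.count(s) > 1:
                raise ConfigError(f"duplicate sample name {s!r}")

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise ConfigError(f"unknown sample {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.sample_index(name)]

    def add_sample(self, name: str, values: np.ndarray,
                   group: str | None = None) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_rows,):
            raise ConfigError("derived sample length does not match row count")
        if name in self.samples:
            raise ConfigError(f"sample {name!r} already exists")
        self.samples.append(name)
        self.matrix = np.column_stack([self.matrix, values])
        if self.groups:
            self.groups.setdefault(group or "derived", []).append(name)

    def set_groups(self, groups: dict[str, list[str]]) -> None:
        flat = [s for g in groups.values() for s in g]
        if sorted(flat) != sorted(self.samples):
            raise ConfigError("sample groups must partition the samples exactly")
        self.groups = {k: list(v) for k, v in groups.items()}
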