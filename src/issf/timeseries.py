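"""Sampled trajectories of signals and model variables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TimeSeries:
    """Named real-valued series on a common strictly increasing time axis."""

    times: np.ndarray
    columns: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        cols = {}
        for name, values in self.columns.items():
            arr = np.asarray(values, dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(
                    f"column {name!r} has length {arr.size}, "
                    f"expected {self.times.size}")
            cols[name] = arr
        self.columns = cols

    def __getitem__(self, name: str) -> np.ndarray:
        return self.columns[name]

    def __contains__(self, name: str) -> bool:
        return name in self.columns

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, **self.columns})

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TimeSeries":
        if "time" not in df.columns:
            raise ValueError("dataframe must have a 'time' column")
        cols = {c: df[c].to_numpy(dtype=float)
                for c in df.columns if c != "time"}
        return cls(times=df["time"].to_numpy(dtype=float), columns=cols)

    @classmethod
    def from_csv(cls, path) -> "TimeSeries":
        return cls.from_dataframe(pd.read_csv(path))
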