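"""Lifetime samples, the embedded carbon-fiber strength datasets, and summaries.

The two built-in datasets are tensile strengths (GPa) of single carbon fibers
tested at gauge lengths of 20 mm and 10 mm respectively (n = 69 each), the
classic Badar & Priest fiber-strength data widely used to benchmark lifetime
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LifetimeSample",
    "SummaryStats",
    "load_builtin",
    "summarize",
    "BUILTIN_DATASETS",
]

# Single carbon fibers under tension, gauge length 20 mm (GPa), n = 69.
_CARBON_FIBER_20MM = (
    1.312, 1.314, 1.479, 1.552, 1.700, 1.803, 1.861, 1.865, 1.944, 1.958,
    1.966, 1.997, 2.006, 2.021, 2.027, 2.055, 2.063, 2.098, 2.14, 2.179,
    2.224, 2.240, 2.253, 2.270, 2.272, 2.274, 2.301, 2.301, 2.359, 2.382,
    2.382, 2.426, 2.434, 2.435, 2.478, 2.490, 2.511, 2.514, 2.535, 2.554,
    2.566, 2.57, 2.586, 2.629, 2.633, 2.642, 2.648, 2.684, 2.697, 2.726,
    2.770, 2.773, 2.800, 2.809, 2.818, 2.821, 2.848, 2.88, 2.954, 3.012,
    3.067, 3.084, 3.090, 3.096, 3.128, 3.233, 3.433, 3.585, 3.585,
)

# Single carbon fibers under tension, gauge length 10 mm (GPa), n = 69.
_CARBON_FIBER_10MM = (
    0.562, 0.564, 0.729, 0.802, 0.950, 1.053, 1.111, 1.115, 1.194, 1.208,
    1.216, 1.247, 1.256, 1.271, 1.277, 1.305, 1.313, 1.348, 1.390, 1.429,
    1.474, 1.490, 1.503, 1.520, 1.522, 1.524, 1.551, 1.551, 1.609, 1.632,
    1.632, 1.676, 1.684, 1.685, 1.728, 1.740, 1.761, 1.764, 1.785, 1.804,
    1.816, 1.824, 1.836, 1.879, 1.883, 1.892, 1.898, 1.934, 1.947, 1.976,
    2.020, 2.023, 2.050, 2.059, 2.068, 2.071, 2.098, 2.130, 2.204, 2.262,
    2.317, 2.334, 2.340, 2.346, 2.378, 2.483, 2.683, 2.835, 2.835,
)

BUILTIN_DATASETS = {
    "carbon_fiber_20mm": _CARBON_FIBER_20MM,
    "carbon_fiber_10mm": _CARBON_FIBER_10MM,
}


@dataclass(frozen=True)
class LifetimeSample:
    """A univariate sample of strictly positive lifetimes.

    Ties are permitted; a sorted view is available through :attr:`sorted_values`.
    """

    values: np.ndarray
    provenance: str = "user"
    _sorted: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float).ravel()
        if arr.size == 0:
            raise ValueError("sample must contain at least one observation")
        if not np.all(np.isfinite(arr)) or not np.all(arr > 0):
            raise ValueError("all observations must be finite and strictly positive")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "_sorted", np.sort(arr))

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def sorted_values(self) -> np.ndarray:
        return self._sorted

    def __len__(self) -> int:
        return self.n

    @classmethod
    def from_file(cls, path: str, provenance: str | None = None) -> "LifetimeSample":
        """Read a single-column numeric text/CSV file (header optional).

        Values may be separated by whitespace, commas or newlines; blank lines
        are skipped; decimal points only.
        """
        with open(path) as fh:
            tokens: list[str] = []
            for line in fh:
                tokens.extend(t for t in line.replace(",", " ").split() if t)
        values = []
        for i, tok in enumerate(tokens):
            try:
                values.append(float(tok))
            except ValueError:
                if i == 0:  # tolerate a single header token
                    continue
                raise ValueError(f"non-numeric token {tok!r} in {path}")
        if not values:
            raise ValueError(f"no numeric data found in {path}")
        return cls(np.asarray(values), provenance=provenance or path)


def load_builtin(name: str) -> LifetimeSample:
    """Return one of the embedded datasets by name.

    Parameters
    ----------
    name : {"carbon_fiber_20mm", "carbon_fiber_10mm"}
    """
    try:
        values = BUILTIN_DATASETS[name]
    except KeyError:
        raise KeyError(
            f"unknown builtin dataset {name!r}; choose from {sorted(BUILTIN_DATASETS)}"
        ) from None
    return LifetimeSample(np.asarray(values), provenance=f"builtin:{name}")


@dataclass(frozen=True)
class SummaryStats:
    """Descriptive summary of a lifetime sample.

    Quartiles use linear interpolation on the sorted data (the convention a
    default statistical summary produces); variance uses the n-1 denominator;
    skewness and kurtosis are the moment coefficients g1 = m3/m2^(3/2) and
    b2 = m4/m2^2 with n-denominator central moments (b2, not excess).
    """

    n: int
    min: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float
    variance: float
    skewness: float
    kurtosis: float

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "n": self.n, "min": self.min, "q1": self.q1, "median": self.median,
                "mean": self.mean, "q3": self.q3, "max": self.max,
                "variance": self.variance, "skewness": self.skewness,
                "kurtosis": self.kurtosis,
            }
        )


def summarize(sample: LifetimeSample) -> SummaryStats:
    """Descriptive statistics of a sample (see :class:`SummaryStats` conventions)."""
    x = sample.values
    if x.size < 2:
        raise ValueError("summary requires at least two observations")
    m = x - x.mean()
    m2 = float(np.mean(m**2))
    m3 = float(np.mean(m**3))
    m4 = float(np.mean(m**4))
    if m2 == 0.0:  # constant sample: shape coefficients undefined
        skew = kurt = float("nan")
    else:
        skew = m3 / m2**1.5
        kurt = m4 / m2**2
    q1, med, q3 = (float(v) for v in np.quantile(x, [0.25, 0.5, 0.75]))
    return SummaryStats(
        n=sample.n,
        min=float(x.min()),
        q1=q1,
        median=med,
        mean=float(x.mean()),
        q3=q3,
        max=float(x.max()),
        variance=float(x.var(ddof=1)),
        skewness=skew,
        kurtosis=kurt,
    )
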