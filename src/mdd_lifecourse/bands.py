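"""Age bands partitioning the simulated life course [18, 65).

Transition hazards are piecewise constant on these bands.  The default
partition uses 5-year bands anchored at age 18; since 47 years is not
divisible by 5 the final band is the short interval [63, 65).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

START_AGE = 18.0
END_AGE = 65.0

DEFAULT_BOUNDARIES = (18.0, 23.0, 28.0, 33.0, 38.0, 43.0, 48.0, 53.0, 58.0, 63.0, 65.0)


@dataclass(frozen=True)
class AgeBands:
    """An ordered partition of [18, 65) into half-open age bands [a, b)."""

    boundaries: tuple[float, ...] = DEFAULT_BOUNDARIES
    _array: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ConfigurationError("boundaries: need at least two ages")
        if b[0] != START_AGE:
            raise ConfigurationError(f"boundaries: first boundary must be {START_AGE}")
        if b[-1] != END_AGE:
            raise ConfigurationError(f"boundaries: last boundary must be {END_AGE}")
        if not np.all(np.diff(b) > 0):
            raise ConfigurationError("boundaries: must be strictly increasing")
        object.__setattr__(self, "boundaries", tuple(float(x) for x in b))
        object.__setattr__(self, "_array", b)

    @classmethod
    def five_year(cls) -> "AgeBands":
        return cls(DEFAULT_BOUNDARIES)

    @property
    def n_bands(self) -> int:
        return len(self.boundaries) - 1

    @property
    def starts(self) -> np.ndarray:
        return self._array[:-1]

    @property
    def ends(self) -> np.ndarray:
        return self._array[1:]

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self._array)

    @property
    def labels(self) -> list[str]:
        return [f"[{s:g},{e:g})" for s, e in zip(self.starts, self.ends)]

    def index_of(self, age):
        """Band index containing ``age``; age 65 maps to the last band.

        Accepts scalars or arrays.
        """
        a = np.asarray(age, dtype=float)
        if np.any(a < START_AGE) or np.any(a > END_AGE):
            raise ValueError(f"age outside [{START_AGE}, {END_AGE}]")
        idx = np.searchsorted(self._array, a, side="right") - 1
        idx = np.clip(idx, 0, self.n_bands - 1)
        return int(idx) if np.isscalar(age) else idx
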