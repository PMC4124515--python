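"""Uniform grid on the elapsed-time half-line, truncated at ``s_max``.

The structuring variable ``s`` (time elapsed since a neuron's last
discharge) lives on ``[0, s_max]``, split into ``n_cells`` half-open
cells ``[i*ds, (i+1)*ds)``.  Cell values are cell-average densities;
coefficients are evaluated at the left nodes ``s_i = i*ds``, which keeps
point-map kernels exact whenever the map lands on a node.

The time step always equals the cell width (``dt = ds``): transport at
unit speed is then an exact one-cell shift, which is what makes the
scheme conservative to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Grid:
    """Discretization of ``[0, s_max]`` with matched time step.

    Parameters
    ----------
    s_max : float
        Domain truncation point (must be positive).
    n_cells : int
        Number of cells; ``ds = s_max / n_cells``.
    """

    s_max: float
    n_cells: int
    ds: float = field(init=False)
    dt: float = field(init=False)

    def __post_init__(self) -> None:
        if self.s_max <= 0:
            raise ValueError(f"s_max must be positive, got {self.s_max}")
        if self.n_cells <= 0:
            raise ValueError(f"n_cells must be positive, got {self.n_cells}")
        ds = self.s_max / self.n_cells
        object.__setattr__(self, "ds", ds)
        object.__setattr__(self, "dt", ds)

    @property
    def nodes(self) -> np.ndarray:
        """Left node of every cell, ``s_i = i * ds``."""
        return np.arange(self.n_cells) * self.ds

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_cells) + 0.5) * self.ds

    def index_of(self, s: float) -> int:
        """Index of the cell containing ``s`` (clipped to the domain)."""
        return int(np.clip(np.floor(s / self.ds), 0, self.n_cells - 1))

    @classmethod
    def from_ds(cls, s_max: float, ds: float) -> "Grid":
        """Grid with cell width as close as possible to ``ds``."""
        n = max(1, int(round(s_max / ds)))
        return cls(s_max=n * ds, n_cells=n)
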