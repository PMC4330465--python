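"""Descriptor covariance analysis: pairwise |ρ|, redundancy screen, chance risk.

The correlation coefficient between two descriptors is computed on columns
centered and scaled to unit variance with the population divisor N:

    ρ = | Σ_i x_{i,1} x_{i,2} / N |

which is exactly the absolute Pearson correlation.  Redundancy screening
lists descriptor pairs whose |ρ| exceeds a cutoff (default 0.7), optionally
counted against anchor descriptors; the chance-correlation risk for K
pairwise comparisons at significance α is 1 − (1 − α)^K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemio import DescriptorMatrix, autoscale

__all__ = [
    "CorrelationMatrix",
    "RedundancyReport",
    "correlation_matrix",
    "redundant_pairs",
    "chance_correlation_risk",
]


@dataclass
class CorrelationMatrix:
    names: list[str]
    rho: np.ndarray  # K×K absolute correlations
    n_obs: int

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        K = len(self.names)
        assert self.rho.shape == (K, K)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.names, columns=self.names)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.rho[self.names.index(a), self.names.index(b)])


@dataclass
class RedundancyReport:
    threshold: float
    pairs: list[tuple[str, str, float]]
    anchor_counts: dict[str, int] = field(default_factory=dict)
    #: descriptors exceeding the threshold against at least one anchor
    flagged_vs_anchors: list[str] = field(default_factory=list)


def correlation_matrix(matrix: DescriptorMatrix | pd.DataFrame | np.ndarray,
                       ) -> CorrelationMatrix:
    """Absolute pairwise correlation matrix of descriptor columns."""
    if isinstance(matrix, DescriptorMatrix):
        names = matrix.column_names
        n = matrix.shape[0]
    elif isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns)
        n = len(matrix)
    else:
        arr = np.asarray(matrix, dtype=float)
        names = [f"x{j}" for j in range(arr.shape[1])]
        n = arr.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    scaled, _ = autoscale(matrix, divisor_mode="population")
    rho = np.abs(scaled.T @ scaled / n)
    np.fill_diagonal(rho, 1.0)
    rho = np.clip((rho + rho.T) / 2.0, 0.0, 1.0)
    return CorrelationMatrix(names=names, rho=rho, n_obs=n)


def redundant_pairs(corr: CorrelationMatrix, threshold: float = 0.7,
                    anchors: list[str] | None = None) -> RedundancyReport:
    """All descriptor pairs with |ρ| above ``threshold``.

    With ``anchors`` given, also counts — per anchor — how many other
    descriptors exceed the threshold against it, and lists every descriptor
    redundant with at least one anchor (the screen used to discard
    size/flexibility duplicates before model building).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    names, rho = corr.names, corr.rho
    pairs = [
        (names[a], names[b], float(rho[a, b]))
        for a in range(len(names))
        for b in range(a + 1, len(names))
        if rho[a, b] > threshold
    ]
    anchor_counts: dict[str, int] = {}
    flagged: set[str] = set()
    if anchors:
        unknown = [a for a in anchors if a not in names]
        if unknown:
            raise KeyError(f"unknown anchor descriptors: {unknown}")
        for a in anchors:
            ai = names.index(a)
            over = [names[j] for j in range(len(names))
                    if j != ai and rho[ai, j] > threshold and names[j] not in anchors]
            anchor_counts[a] = len(over)
            flagged.update(over)
    return RedundancyReport(
        threshold=threshold,
        pairs=sorted(pairs, key=lambda p: -p[2]),
        anchor_counts=anchor_counts,
        flagged_vs_anchors=sorted(flagged),
    )


def chance_correlation_risk(n_comparisons: int, alpha: float = 0.05) -> float:
    """Probability of at least one spurious significant correlation.

    For K independent pairwise comparisons each tested at level α the
    family-wise chance-correlation risk is 1 − (1 − α)^K.
    """
    if n_comparisons < 1:
        raise ValueError(f"need K >= 1 comparisons, got {n_comparisons}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    return 1.0 - (1.0 - alpha) ** n_comparisons
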