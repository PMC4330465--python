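"""Synthetic studies with known ground truth.

Emulates the statistical structure the pipeline consumes, with chemistry
abstracted away:

* a combinatorial building-block library (default: four positions whose
  fragment counts multiply to 144 candidates, of which 18 are selected —
  the shape of the original design),
* an additive latent fragment-effect response
  y = intercept + Σ β(fragment) + ε,  ε ~ N(0, σ²) i.i.d., with the true
  β and σ retained for recovery tests; the default σ of 0.45 pIC50 units
  matches a typical half-log-unit assay/model error, and
* quantitative descriptor blocks drawn from a Gaussian copula with a
  user-specified correlation structure, to mimic confounded descriptor
  pairs (e.g. two electronic descriptors correlated at 0.94).

A single master seed deterministically derives per-stage child streams, so
regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chemio import ActivityTable, CompoundRecord, DescriptorMatrix, pic50_to_ic50
from .design import BuildingBlockLibrary, CandidateSet, Selection, d_optimal_select, enumerate_candidates

__all__ = [
    "SyntheticStudy",
    "CorrelatedBlockSpec",
    "generate_study",
    "generate_descriptors",
    "DEFAULT_LIBRARY_SHAPE",
]

#: library shape of the reference design: 4 positions, 144 combinations
DEFAULT_LIBRARY_SHAPE: tuple[int, ...] = (4, 3, 3, 4)
DEFAULT_SIGMA = 0.45
DEFAULT_INTERCEPT = 4.0  # mid-micromolar baseline potency on the pIC50 scale


def _child_seeds(master: int, n: int) -> list[int]:
    """Derive per-stage child seeds (< 2^31) from one master seed."""
    ss = np.random.SeedSequence(master)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


@dataclass
class SyntheticStudy:
    library: BuildingBlockLibrary
    beta: dict[str, float]           # "pos:frag" -> additive effect
    sigma: float
    intercept: float
    seed: int
    candidates: CandidateSet
    selection: Selection | None
    activities: ActivityTable        # selected (or all) candidates with y
    y_true: pd.Series                # noise-free responses, same index
    descriptors: DescriptorMatrix | None = None

    @property
    def indicator_frame(self) -> pd.DataFrame:
        """Full binary indicator rows for the compounds in ``activities``."""
        idx = [int(i) for i in self.activities.ids]
        frame = self.candidates.indicator_matrix.values.iloc[idx]
        frame.index = self.activities.ids
        return frame


def generate_study(library_shape: Sequence[int] = DEFAULT_LIBRARY_SHAPE,
                   beta_spec: Mapping[str, float] | float | None = None,
                   sigma: float = DEFAULT_SIGMA,
                   n_select: int | None = 18,
                   seed: int = 0,
                   intercept: float = DEFAULT_INTERCEPT,
                   n_starts: int = 20) -> SyntheticStudy:
    """Simulate a designed SAR study with additive fragment effects.

    ``beta_spec`` is either an explicit {"pos:frag": effect} map, a scalar
    scale s (effects drawn i.i.d. N(0, s²) and centered within each
    position), or None for the default scale 0.5.  ``n_select`` picks a
    D-optimal subset of that size; None keeps all candidates.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    lib = BuildingBlockLibrary.from_shape(library_shape)
    cands = enumerate_candidates(lib)
    if n_select is not None and not (0 < n_select <= len(cands)):
        raise ValueError(f"n_select={n_select} infeasible for {len(cands)} candidates")

    seeds = _child_seeds(seed, 3)
    rng_beta = np.random.default_rng(seeds[0])
    rng_noise = np.random.default_rng(seeds[1])

    if beta_spec is None or np.isscalar(beta_spec):
        scale = 0.5 if beta_spec is None else float(beta_spec)
        beta: dict[str, float] = {}
        for p in lib.positions:
            draws = rng_beta.normal(0.0, scale, size=len(lib.fragments[p]))
            draws -= draws.mean()  # identifiable: effects sum to zero per position
            for f, d in zip(lib.fragments[p], draws):
                beta[f"{p}:{f}"] = float(d)
    else:
        beta = {str(k): float(v) for k, v in beta_spec.items()}

    if n_select is not None and n_select < len(cands):
        selection = d_optimal_select(cands, n_select, n_starts=n_starts, seed=seeds[2])
        chosen = selection.selected_indices
    else:
        selection = None
        chosen = list(range(len(cands)))

    records: list[CompoundRecord] = []
    y_true = {}
    for idx in chosen:
        cand = cands.candidates[idx]
        mu = intercept + sum(beta.get(f"{p}:{f}", 0.0)
                             for p, f in zip(lib.positions, cand))
        y = mu + rng_noise.normal(0.0, sigma)
        cid = str(idx)
        y_true[cid] = mu
        records.append(CompoundRecord(
            id=cid, name="-".join(cand),
            ic50=pic50_to_ic50(y), pic50=y,
            fragments=dict(zip(lib.positions, cand)),
        ))
    table = ActivityTable(records, role="train", set_label="synthetic")
    return SyntheticStudy(
        library=lib, beta=beta, sigma=sigma, intercept=intercept, seed=seed,
        candidates=cands, selection=selection, activities=table,
        y_true=pd.Series(y_true, name="y_true"),
    )


@dataclass
class CorrelatedBlockSpec:
    """Block-structured target correlation for quantitative descriptors."""

    block_sizes: list[int]
    within: float | list[float] = 0.0   # target correlation inside each block
    between: float = 0.0                # cross-block correlation
    names: list[str] | None = None

    def target_matrix(self) -> np.ndarray:
        within = self.within if isinstance(self.within, list) else [self.within] * len(self.block_sizes)
        if len(within) != len(self.block_sizes):
            raise ValueError("one within-block correlation per block required")
        K = sum(self.block_sizes)
        C = np.full((K, K), self.between, dtype=float)
        ofs = 0
        for size, w in zip(self.block_sizes, within):
            C[ofs:ofs + size, ofs:ofs + size] = w
            ofs += size
        np.fill_diagonal(C, 1.0)
        return C


def generate_descriptors(n_rows: int, spec: CorrelatedBlockSpec, seed: int = 0,
                         row_ids: Sequence[str] | None = None) -> DescriptorMatrix:
    """Sample a quantitative descriptor matrix hitting a target correlation.

    Gaussian copula: rows are multivariate normal with the requested target
    correlation matrix (validated positive semi-definite first), so realized
    pairwise correlations converge to the target at the usual 1/sqrt(n)
    Monte-Carlo rate.
    """
    C = spec.target_matrix()
    eig = np.linalg.eigvalsh(C)
    if eig.min() < -1e-10:
        raise ValueError(
            f"target correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eig.min():.3g})"
        )
    rng = np.random.default_rng(_child_seeds(seed, 1)[0])
    L = np.linalg.cholesky(C + 1e-12 * np.eye(C.shape[0]))
    X = rng.standard_normal((n_rows, C.shape[0])) @ L.T
    names = spec.names or [f"d{j+1}" for j in range(C.shape[0])]
    idx = list(row_ids) if row_ids is not None else [str(i) for i in range(n_rows)]
    return DescriptorMatrix(pd.DataFrame(X, index=idx, columns=names),
                            kind="quantitative")
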