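"""Statistical molecular design over combinatorial building-block libraries.

A candidate molecule is one fragment choice per variable position (e.g.
pIa/pIb/pII/pIII).  Candidates are described by binary fragment indicators
("conditional" descriptors).  A D-optimal subset of size n maximises
det(Xsel' Xsel) on the centered/unit-variance indicator matrix, spreading
the selected molecules so fragment effects can be estimated independently;
the condition number (largest/smallest singular value, 1 for a perfectly
orthogonal design) and per-fragment occurrence counts diagnose the result.

Under the full one-column-per-fragment encoding the indicator blocks are
exactly collinear after centering (each position's block sums to 1 per
row), so optimisation and the condition number are computed by default on
a reduced encoding that drops one reference fragment per position; reports
keep full-encoding names.  The full encoding remains available via a
pseudo-determinant over the non-null eigenvalues.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BuildingBlockLibrary",
    "CandidateSet",
    "DesignMatrix",
    "Selection",
    "enumerate_candidates",
    "d_optimal_select",
    "condition_number",
    "log_det_information",
    "balance_report",
]

_RIDGE = 1e-8  # jitter on X'X for ranking candidate swaps only
_SING_TOL = 1e-9


@dataclass
class BuildingBlockLibrary:
    positions: list[str]
    fragments: Mapping[str, Sequence[str]]

    def __post_init__(self) -> None:
        for p in self.positions:
            frs = list(self.fragments.get(p, []))
            if not frs:
                raise ValueError(f"position {p!r} has no fragments")
            if len(set(frs)) != len(frs):
                raise ValueError(f"duplicate fragment labels at position {p!r}")

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(self.fragments[p]) for p in self.positions)

    @property
    def n_candidates(self) -> int:
        return int(np.prod(self.shape))

    @classmethod
    def from_shape(cls, sizes: Sequence[int],
                   position_labels: Sequence[str] | None = None) -> "BuildingBlockLibrary":
        labels = list(position_labels) if position_labels else [f"p{i+1}" for i in range(len(sizes))]
        frags = {p: [f"{p}_f{j+1}" for j in range(k)] for p, k in zip(labels, sizes)}
        return cls(positions=labels, fragments=frags)


@dataclass
class DesignMatrix:
    """Binary fragment-indicator matrix over a candidate set."""

    values: pd.DataFrame  # rows: candidate index, cols: "pos:frag"
    position_blocks: Mapping[str, list[str]]  # position -> its column names
    encoding: Literal["full", "reduced"] = "full"

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def reduced(self) -> pd.DataFrame:
        """Drop the first (reference) fragment column of each position."""
        drop = [cols[0] for cols in self.position_blocks.values() if len(cols) > 1]
        return self.values.drop(columns=drop)


@dataclass
class CandidateSet:
    library: BuildingBlockLibrary
    candidates: list[tuple[str, ...]]  # one fragment label per position
    indicator_matrix: DesignMatrix

    def __len__(self) -> int:
        return len(self.candidates)


@dataclass
class Selection:
    selected_indices: list[int]
    log_det: float
    condition_number: float
    balance: dict[str, int]
    provenance: dict = field(default_factory=dict)


def enumerate_candidates(lib: BuildingBlockLibrary) -> CandidateSet:
    """Full factorial enumeration in lexicographic position/fragment order."""
    frag_lists = [list(lib.fragments[p]) for p in lib.positions]
    candidates = list(itertools.product(*frag_lists))
    columns: list[str] = []
    blocks: dict[str, list[str]] = {}
    for p, frs in zip(lib.positions, frag_lists):
        blocks[p] = [f"{p}:{f}" for f in frs]
        columns.extend(blocks[p])
    X = np.zeros((len(candidates), len(columns)))
    col_index = {c: j for j, c in enumerate(columns)}
    for i, cand in enumerate(candidates):
        for p, f in zip(lib.positions, cand):
            X[i, col_index[f"{p}:{f}"]] = 1.0
    dm = DesignMatrix(pd.DataFrame(X, columns=columns), blocks, encoding="full")
    return CandidateSet(library=lib, candidates=candidates, indicator_matrix=dm)


def _scale_columns(X: np.ndarray) -> np.ndarray:
    """Center/unit-variance scale; zero-variance columns become all-zero."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe


def log_det_information(X_scaled_sel: np.ndarray, pseudo: bool = False) -> float:
    """log det(Xsel' Xsel); −inf when singular (or pseudo-det over λ > tol)."""
    info = X_scaled_sel.T @ X_scaled_sel
    if pseudo:
        lam = np.linalg.eigvalsh(info)
        lam = lam[lam > _SING_TOL * max(1.0, lam.max(initial=0.0))]
        return float(np.sum(np.log(lam))) if lam.size else -math.inf
    sign, ld = np.linalg.slogdet(info)
    return float(ld) if sign > 0 else -math.inf


def condition_number(X) -> float:
    """Ratio of largest to smallest singular value of the autoscaled matrix.

    Columns are centered and scaled to unit variance over the given rows
    first; a perfectly orthogonal design scores 1, and any singular (e.g.
    constant or duplicated-column) matrix scores +inf.
    """
    if isinstance(X, DesignMatrix):
        arr = X.to_numpy()
    elif isinstance(X, pd.DataFrame):
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
    if arr.size == 0 or arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a matrix with at least 2 columns")
    sd = arr.std(axis=0, ddof=0)
    if np.any(sd <= 0):
        return math.inf
    s = np.linalg.svd(_scale_columns(arr), compute_uv=False)
    if s[-1] <= _SING_TOL * s[0]:
        return math.inf
    return float(s[0] / s[-1])


def _fedorov_sweep(Xs: np.ndarray, selected: np.ndarray) -> tuple[np.ndarray, bool]:
    """One steepest-ascent pass over all single swaps.

    Uses the classical determinant-ratio for exchanging selected row x_i
    against candidate x_j on the (ridged) information matrix M:

        det(M') / det(M) = (1 + d_jj)(1 − d_ii) + d_ij²

    with d_ab = x_a' M⁻¹ x_b, evaluated for all pairs at once.
    """
    n_cand = Xs.shape[0]
    in_sel = np.zeros(n_cand, dtype=bool)
    in_sel[selected] = True
    complement = np.flatnonzero(~in_sel)

    M = Xs[selected].T @ Xs[selected] + _RIDGE * np.eye(Xs.shape[1])
    V = Xs @ np.linalg.inv(M)          # n×K
    d_full = np.einsum("ik,jk->ij", V, Xs)  # d_ab for all candidate pairs
    d_ii = d_full[selected, selected]
    d_jj = d_full[complement, complement]
    d_ij = d_full[np.ix_(selected, complement)]
    ratio = (1.0 + d_jj)[None, :] * (1.0 - d_ii)[:, None] + d_ij**2

    pos, jc = np.unravel_index(np.argmax(ratio), ratio.shape)
    if ratio[pos, jc] <= 1.0 + 1e-10:
        return selected, False
    out = selected.copy()
    out[pos] = complement[jc]
    return out, True


def d_optimal_select(design: DesignMatrix | CandidateSet, n_select: int,
                     n_starts: int = 50, seed: int = 0,
                     encoding: Literal["reduced", "full"] = "reduced",
                     lib: BuildingBlockLibrary | None = None) -> Selection:
    """Fedorov single-swap exchange for a D-optimal n-subset.

    The candidate indicator matrix is centered and scaled to unit variance
    (over all candidates) before optimisation.  ``n_starts`` random initial
    subsets are each improved by steepest-ascent single swaps until no swap
    raises log det(Xsel'Xsel); the best local optimum wins, with ties broken
    on the lexicographically smallest selected index set.  Deterministic for
    a given ``seed``.
    """
    if isinstance(design, CandidateSet):
        lib = lib or design.library
        dm = design.indicator_matrix
        cands = design.candidates
    else:
        dm = design
        cands = None
    frame = dm.reduced() if encoding == "reduced" else dm.values
    pseudo = encoding == "full"
    Xs = _scale_columns(frame.to_numpy(dtype=float))
    n_cand, n_col = Xs.shape
    if not (0 < n_select <= n_cand):
        raise ValueError(f"n_select {n_select} out of range (1..{n_cand})")

    warn = None
    if n_select < n_col:
        warn = (f"n_select={n_select} < {n_col} design columns: "
                "Xsel'Xsel is singular, log_det reported as -inf")

    if n_select == n_cand:
        best = np.arange(n_cand)
    else:
        rng = np.random.default_rng(seed)
        best, best_obj = None, -math.inf
        for _ in range(n_starts):
            sel = np.sort(rng.choice(n_cand, size=n_select, replace=False))
            improving = True
            while improving:
                sel, improving = _fedorov_sweep(Xs, sel)
            obj = log_det_information(Xs[sel], pseudo=pseudo)
            if obj == -math.inf:
                info = Xs[sel].T @ Xs[sel] + _RIDGE * np.eye(n_col)
                obj_rank = np.linalg.slogdet(info)[1] - 1e6  # rank singular below regular
            else:
                obj_rank = obj
            key = sorted(sel.tolist())
            if best is None or obj_rank > best_obj + 1e-9 or (
                abs(obj_rank - best_obj) <= 1e-9 and key < sorted(best.tolist())
            ):
                best, best_obj = np.array(key), obj_rank
        best = np.sort(best)

    X_best = Xs[best]
    ld = log_det_information(X_best, pseudo=pseudo)
    # condition number on the selected rows, rescaled over the selection
    sub = frame.iloc[best]
    try:
        cn = condition_number(sub)
    except ValueError:
        cn = math.inf

    balance: dict[str, int] = {}
    if cands is not None and lib is not None:
        for idx in best:
            for p, f in zip(lib.positions, cands[idx]):
                balance[f"{p}:{f}"] = balance.get(f"{p}:{f}", 0) + 1
    else:
        full = dm.to_numpy()[best]
        balance = {c: int(s) for c, s in zip(dm.values.columns, full.sum(axis=0))}

    prov = {"seed": seed, "n_starts": n_starts, "encoding": encoding}
    if warn:
        prov["warning"] = warn
    return Selection(
        selected_indices=[int(i) for i in best],
        log_det=ld,
        condition_number=cn,
        balance=balance,
        provenance=prov,
    )


def balance_report(sel: Selection, lib: BuildingBlockLibrary,
                   min_occurrence: int = 2) -> dict:
    """Per-fragment occurrence counts with a minimum-representation verdict.

    A design is balanced when every building block appears at least
    ``min_occurrence`` times among the selected molecules, so each fragment
    effect rests on repeated observations.
    """
    if not sel.selected_indices:
        raise ValueError("empty selection")
    n = len(sel.selected_indices)
    counts: dict[str, dict[str, int]] = {}
    failing: list[str] = []
    for p in lib.positions:
        counts[p] = {}
        for f in lib.fragments[p]:
            c = sel.balance.get(f"{p}:{f}", 0)
            counts[p][f] = c
            if c < min_occurrence:
                failing.append(f"{p}:{f}")
        assert sum(counts[p].values()) == n, "position counts must sum to n_select"
    return {
        "counts": counts,
        "min_occurrence": min_occurrence,
        "verdict": "pass" if not failing else "fail",
        "failing_fragments": failing,
    }
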