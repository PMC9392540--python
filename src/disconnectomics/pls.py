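"""Nonrotated (contrast-driven) behavioral PLS with permutation and
bootstrap-ratio inference.

Both blocks are column z-scored, so the cross-block matrix
``R = Yz' Xz / (n-1)`` holds Pearson correlations between each behavioral
variable and each voxel. A latent variable is defined by an a-priori unit
contrast ``c`` on the behavioral block: its brain salience is ``v = R' c``,
its strength ``s = ||v||``, and subject brain scores are the projection of
the z-scored brain block onto ``v / s``. With the identity contrast set,
salience k is exactly the mass-univariate correlation map of behavior k —
a property the test suite uses as an oracle.

Significance of each latent variable is assessed by permuting subject
rows of the behavioral block; voxel-level reliability by bootstrap
resampling subjects and forming bootstrap ratios (pseudo-z) = observed
salience / bootstrap SE. With fixed contrasts there is no axis rotation
or sign ambiguity across resamples, so no Procrustes alignment is needed.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .disconnectome import DisconnectomeMap
from .volumes import ImageVolume

log = logging.getLogger(__name__)

__all__ = [
    "BrainMatrix",
    "BehaviorMatrix",
    "ContrastSet",
    "PLSResult",
    "build_analysis_mask",
    "build_brain_matrix",
    "behavior_matrix_from_table",
    "zscore_columns",
    "nonrotated_pls",
    "permutation_test",
    "bootstrap_ratios",
    "salience_to_volume",
    "run_pls",
]


@dataclasses.dataclass
class BrainMatrix:
    """Stacked subject x voxel brain block restricted to the analysis mask."""

    X: np.ndarray                 # subjects x voxels
    mask_index: np.ndarray        # flat voxel indices into the grid
    grid: ImageVolume             # reference grid (shape + affine)
    subject_ids: list[str] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class BehaviorMatrix:
    Y: np.ndarray                 # subjects x b
    names: tuple[str, ...]


@dataclasses.dataclass
class ContrastSet:
    """A-priori contrasts, one unit-normalized column per latent variable."""

    C: np.ndarray                 # b x k

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2:
            raise ValueError("contrast matrix must be 2D (behaviors x contrasts)")
        norms = np.linalg.norm(C, axis=0)
        if np.any(norms == 0):
            raise ValueError("contrast set contains a zero column")
        self.C = C / norms

    @classmethod
    def identity(cls, b: int) -> "ContrastSet":
        """One mean-effect contrast per behavioral variable."""
        return cls(np.eye(b))


@dataclasses.dataclass
class PLSResult:
    salience: np.ndarray          # voxels x k
    strength: np.ndarray          # (k,)
    brain_scores: np.ndarray      # subjects x k
    contrast_names: tuple[str, ...] = ()
    perm_p: np.ndarray | None = None
    boot_se: np.ndarray | None = None
    bsr: np.ndarray | None = None
    n_perm: int = 0
    n_boot: int = 0
    seed: int | None = None
    n_boot_redraws: int = 0
    n_zero_se: int = 0


def build_analysis_mask(maps: list[DisconnectomeMap]) -> np.ndarray:
    """Flat indices of voxels nonzero in >=1 subject with nonzero variance."""
    if len(maps) < 2:
        raise ValueError("need at least 2 subjects to build an analysis mask")
    stack = np.stack([m.data.ravel() for m in maps])
    keep = (stack != 0).any(axis=0) & (stack.var(axis=0) > 0)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError(
            "analysis mask is empty: no voxel varies across subjects"
        )
    return idx


def build_brain_matrix(maps: list[DisconnectomeMap]) -> BrainMatrix:
    idx = build_analysis_mask(maps)
    X = np.stack([m.data.ravel()[idx] for m in maps])
    return BrainMatrix(
        X=X,
        mask_index=idx,
        grid=maps[0].volume,
        subject_ids=[m.subject_id for m in maps],
    )


def behavior_matrix_from_table(
    table: pd.DataFrame, columns: tuple[str, ...] = ("female", "age", "moca")
) -> tuple[BehaviorMatrix, np.ndarray]:
    """Extract the behavioral block; subjects with missing values are dropped.

    Returns the matrix and the boolean row-keep mask (so callers can align
    the brain block).
    """
    sub = table.loc[:, list(columns)]
    keep = ~sub.isna().any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropping %d subjects with missing behavioral values", dropped)
    Y = sub.loc[keep].to_numpy(dtype=float)
    return BehaviorMatrix(Y=Y, names=tuple(columns)), keep.to_numpy()


def zscore_columns(M: np.ndarray) -> np.ndarray:
    """Column-standardize: mean 0, sample SD 1 (denominator n-1)."""
    M = np.asarray(M, dtype=float)
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError(
            f"{int((sd == 0).sum())} constant column(s); z-scoring undefined"
        )
    return (M - M.mean(axis=0)) / sd


def _zscore_allow_constant(M: np.ndarray) -> np.ndarray:
    """Column z-score with constant columns mapped to zero.

    Used inside bootstrap resamples: a voxel constant within one resample
    contributes zero correlation there instead of forcing a redraw.
    """
    M = np.asarray(M, dtype=float)
    sd = M.std(axis=0, ddof=1)
    out = M - M.mean(axis=0)
    nz = sd > 0
    out[:, nz] /= sd[nz]
    out[:, ~nz] = 0.0
    return out


def _saliences(Xz: np.ndarray, Yz: np.ndarray, C: np.ndarray) -> np.ndarray:
    """v_k = R' c_k stacked as voxels x k, with R = Yz' Xz / (n-1)."""
    n = Xz.shape[0]
    return Xz.T @ (Yz @ C) / (n - 1)


def _coerce(X, Y, C):
    Xa = X.X if isinstance(X, BrainMatrix) else np.asarray(X, dtype=float)
    Ya = Y.Y if isinstance(Y, BehaviorMatrix) else np.asarray(Y, dtype=float)
    Ca = C.C if isinstance(C, ContrastSet) else ContrastSet(np.asarray(C, float)).C
    if Xa.shape[0] != Ya.shape[0]:
        raise ValueError(
            f"subject mismatch: brain block has {Xa.shape[0]} rows, "
            f"behavior block {Ya.shape[0]}"
        )
    if Xa.shape[0] < 3:
        raise ValueError("PLS needs at least 3 subjects")
    return Xa, Ya, Ca


def nonrotated_pls(X, Y, C) -> PLSResult:
    """Point estimates: saliences, LV strengths, subject brain scores."""
    Xa, Ya, Ca = _coerce(X, Y, C)
    Xz = _zscore_allow_constant(Xa)
    Yz = zscore_columns(Ya)
    V = _saliences(Xz, Yz, Ca)
    s = np.linalg.norm(V, axis=0)
    scores = np.zeros((Xa.shape[0], Ca.shape[1]))
    nz = s > 0
    if nz.any():
        scores[:, nz] = Xz @ (V[:, nz] / s[nz])
    return PLSResult(salience=V, strength=s, brain_scores=scores)


def permutation_test(X, Y, C, n_perm: int = 1000, seed: int = 0) -> np.ndarray:
    """Permutation p-value per latent variable.

    Rows of Y are permuted jointly against the fixed brain block, Y is
    re-z-scored, and the LV strength recomputed; the p-value uses the
    add-one smoothing (1 + #exceedances) / (1 + n_perm), so p is never 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Xa, Ya, Ca = _coerce(X, Y, C)
    Xz = _zscore_allow_constant(Xa)
    Yz = zscore_columns(Ya)
    s_obs = np.linalg.norm(_saliences(Xz, Yz, Ca), axis=0)
    rng = np.random.default_rng(seed)
    n = Xa.shape[0]
    count = np.zeros(Ca.shape[1], dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Yzp = zscore_columns(Ya[perm])
        s_perm = np.linalg.norm(_saliences(Xz, Yzp, Ca), axis=0)
        count += s_perm >= s_obs
    return (1 + count) / (1 + n_perm)


def bootstrap_ratios(
    X, Y, C, n_boot: int = 1000, seed: int = 0, max_redraw: int = 1000
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Bootstrap SEs and bootstrap-ratio (pseudo-z) maps per latent variable.

    Subjects are resampled with replacement, the same resample applied to
    both blocks, and both re-z-scored. A resample with fewer than 3
    distinct subjects or a constant behavioral column is redrawn (counted);
    brain voxels constant within a resample contribute zero. Voxels with
    zero bootstrap SE get bsr = 0 and are counted in the returned flag.

    Returns (boot_se, bsr, n_redraws, n_zero_se).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    Xa, Ya, Ca = _coerce(X, Y, C)
    Xz = _zscore_allow_constant(Xa)
    Yz = zscore_columns(Ya)
    V_obs = _saliences(Xz, Yz, Ca)
    rng = np.random.default_rng(seed)
    n = Xa.shape[0]
    V_boot = np.empty((n_boot,) + V_obs.shape)
    n_redraws = 0
    for b in range(n_boot):
        for attempt in range(max_redraw + 1):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(idx)) >= 3 and not np.any(
                Ya[idx].std(axis=0, ddof=1) == 0
            ):
                break
            n_redraws += 1
        else:
            raise RuntimeError(
                "could not draw a valid bootstrap resample "
                f"(>= 3 distinct subjects, non-constant behavior) in {max_redraw} tries"
            )
        Xb = _zscore_allow_constant(Xa[idx])
        Yb = zscore_columns(Ya[idx])
        V_boot[b] = _saliences(Xb, Yb, Ca)
    boot_se = V_boot.std(axis=0, ddof=1)
    # float fuzz: an SE at rounding-noise level means the resampled salience
    # never actually varied, so the ratio is meaningless there
    zero = boot_se <= 1e-12
    boot_se[zero] = 0.0
    bsr = np.zeros_like(V_obs)
    bsr[~zero] = V_obs[~zero] / boot_se[~zero]
    n_zero_se = int(zero.sum())
    if n_zero_se:
        log.info("%d voxel/contrast cells had zero bootstrap SE (bsr set to 0)",
                 n_zero_se)
    return boot_se, bsr, n_redraws, n_zero_se


def salience_to_volume(
    vec: np.ndarray, mask_index: np.ndarray, grid: ImageVolume
) -> ImageVolume:
    """Scatter a masked voxel vector back into a full volume (0 elsewhere)."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape[0] != mask_index.shape[0]:
        raise ValueError(
            f"vector length {vec.shape[0]} != mask size {mask_index.shape[0]}"
        )
    out = np.zeros(int(np.prod(grid.shape)))
    out[mask_index] = vec
    return grid.like(out.reshape(grid.shape))


def run_pls(
    maps: list[DisconnectomeMap],
    behavior: pd.DataFrame,
    columns: tuple[str, ...] = ("female", "age", "moca"),
    contrasts: ContrastSet | None = None,
    n_perm: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[PLSResult, BrainMatrix]:
    """Full nonrotated behavioral PLS on a cohort of disconnectome maps.

    ``behavior`` rows must align with ``maps``; subjects with missing
    behavioral values are dropped from both blocks. Permutation and
    bootstrap use independent streams derived from ``seed``.
    """
    if len(maps) != len(behavior):
        raise ValueError("behavior table and map list must align row-for-row")
    Ymat, keep = behavior_matrix_from_table(behavior, columns)
    kept_maps = [m for m, k in zip(maps, keep) if k]
    Xmat = build_brain_matrix(kept_maps)
    C = contrasts if contrasts is not None else ContrastSet.identity(len(columns))
    res = nonrotated_pls(Xmat, Ymat, C)
    seed_perm, seed_boot = _spawn_seeds(seed, 2)
    res.perm_p = permutation_test(Xmat, Ymat, C, n_perm=n_perm, seed=seed_perm)
    res.boot_se, res.bsr, res.n_boot_redraws, res.n_zero_se = bootstrap_ratios(
        Xmat, Ymat, C, n_boot=n_boot, seed=seed_boot
    )
    res.contrast_names = tuple(columns)
    res.n_perm, res.n_boot, res.seed = n_perm, n_boot, seed
    return res, Xmat


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds (< 2**31) derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]
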