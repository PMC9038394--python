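"""A-SMOTE: synthesize minority candidates, filter by nearest-class distance,
then purge the half of accepted candidates closest to the majority class.

The resampler runs in three steps on a two-class dataset with z minority and
r majority rows (z <= r):

1. *Synthesis.* N = 2(r - z) + z = 2r - z candidates are built by SMOTE-style
   interpolation: seeds cycle round-robin through the minority rows, each
   candidate interpolates between its seed and one of the seed's k nearest
   minority neighbours with a uniform gap u in [0, 1).  A candidate is then
   kept only if it is strictly closer (minimum squared distance) to the
   minority set than to the majority set; ties reject.
2. *Rapprochement.* For every accepted candidate the summed squared distance
   to all minority rows (``min_rap``) and to all majority rows (``maj_rap``)
   is computed; their batch totals L and H are recorded for audit.
3. *Denoising.* The floor(a/2) accepted candidates with the smallest
   ``maj_rap`` — i.e. closest to the majority cloud — are removed as noise;
   the survivors join the dataset with the minority label.

Distances are sums of squared per-coordinate differences (no square root);
acceptance decisions are invariant under the square root since it is a
strictly monotone transform.  Continuous columns are min-max scaled to [0, 1]
and categorical columns one-hot expanded before any distance computation, so
that features with incomparable units (years vs. mg/dl) contribute
comparably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import ClassSplit, ColumnSpec, Dataset, class_split
from .errors import ImbalanceError, TooFewMinorityError, ValidationError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# mixed-type encoding for distance computations
# ---------------------------------------------------------------------------

class MixedEncoder:
    """Min-max scale continuous columns, one-hot expand categorical ones.

    Fitted on the union of minority and majority rows of the partition being
    resampled; a constant continuous column maps to 0.
    """

    def __init__(self, columns: list[ColumnSpec]):
        self.columns = columns
        self._lo: np.ndarray | None = None
        self._span: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "MixedEncoder":
        cont = [j for j, c in enumerate(self.columns) if not c.is_categorical]
        self._cont = cont
        if cont:
            sub = X[:, cont]
            self._lo = sub.min(axis=0)
            span = sub.max(axis=0) - self._lo
            self._span = np.where(span > 0, span, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        parts = []
        for j, col in enumerate(self.columns):
            v = X[:, j]
            if col.is_categorical:
                codes = np.asarray(col.categories)
                parts.append((v[:, None] == codes[None, :]).astype(float))
            else:
                k = self._cont.index(j)
                parts.append(((v - self._lo[k]) / self._span[k])[:, None])
        return np.hstack(parts)


# ---------------------------------------------------------------------------
# batch container
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBatch:
    """Candidate minority rows with provenance.

    ``index`` records each candidate's position in the originally generated
    batch; it is preserved through filtering so denoising tie-breaks are
    well defined.
    """

    Xs: np.ndarray
    seed_idx: np.ndarray
    neighbor_idx: np.ndarray
    gap: np.ndarray
    index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.Xs = np.atleast_2d(np.asarray(self.Xs, dtype=float))
        if self.index is None:
            self.index = np.arange(self.Xs.shape[0])

    def __len__(self) -> int:
        return self.Xs.shape[0]

    def take(self, rows: np.ndarray) -> "SyntheticBatch":
        return SyntheticBatch(
            self.Xs[rows],
            np.asarray(self.seed_idx)[rows],
            np.asarray(self.neighbor_idx)[rows],
            np.asarray(self.gap)[rows],
            np.asarray(self.index)[rows],
        )


@dataclass
class ResampleResult:
    """Augmented dataset plus the bookkeeping of every A-SMOTE step."""

    augmented: Dataset
    n_requested: int
    n_accepted: int
    n_removed: int
    accepted_majrap: np.ndarray
    L: float = 0.0
    H: float = 0.0
    n_original_minority: int = 0
    n_original_majority: int = 0


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def synth_count(r: int, z: int) -> int:
    """Number of candidates to synthesize: N = 2(r - z) + z = 2r - z."""
    if z < 1:
        raise ImbalanceError("minority count z must be >= 1")
    if z > r:
        raise ImbalanceError(f"minority count z={z} exceeds majority count r={r}")
    return 2 * r - z


def min_sq_dist(p: np.ndarray, S: np.ndarray) -> float:
    """Minimum over rows s of S of the summed squared difference to p."""
    p = np.asarray(p, dtype=float)
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if S.size == 0:
        raise ValidationError("reference set S is empty")
    if S.shape[1] != p.shape[-1]:
        raise ValidationError("dimension mismatch between p and S")
    return float(((S - p) ** 2).sum(axis=1).min())


def min_rap(s: np.ndarray, S_m: np.ndarray) -> float:
    """Rapprochement to the minority class: sum over ALL minority rows of the
    summed squared coordinate differences."""
    S_m = np.atleast_2d(np.asarray(S_m, dtype=float))
    if S_m.size == 0:
        raise ValidationError("minority set is empty")
    return float(((S_m - np.asarray(s, dtype=float)) ** 2).sum())


def maj_rap(s: np.ndarray, S_a: np.ndarray) -> float:
    """Rapprochement to the majority class (same double sum over S_a)."""
    S_a = np.atleast_2d(np.asarray(S_a, dtype=float))
    if S_a.size == 0:
        raise ValidationError("majority set is empty")
    return float(((S_a - np.asarray(s, dtype=float)) ** 2).sum())


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def generate_candidates(
    split: ClassSplit,
    N: int,
    k_neighbors: int,
    rng: np.random.Generator,
) -> SyntheticBatch:
    """SMOTE-style interpolation producing exactly N candidates.

    Seeds cycle round-robin through the minority rows (per-seed counts differ
    by at most one); for each candidate one of the seed's ``k_neighbors``
    nearest minority neighbours (Euclidean, in the scaled/one-hot space) is
    drawn uniformly, the gap u is uniform on [0, 1), continuous columns are
    interpolated as seed + u * (neighbor - seed), and categorical columns are
    copied from the nearer parent along the segment (u <= 0.5 -> seed).
    """
    z = split.z
    if z < 2:
        raise TooFewMinorityError("cannot interpolate a single minority point")
    if not 1 <= k_neighbors <= z - 1:
        raise ImbalanceError(f"k_neighbors must be in [1, z-1]=[1, {z - 1}]")

    enc = MixedEncoder(split.columns).fit(np.vstack([split.S_m, split.S_a]))
    E_m = enc.transform(split.S_m)
    # z x k table of each minority row's nearest minority neighbours
    d2 = ((E_m[:, None, :] - E_m[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k_neighbors]

    seeds = np.arange(N) % z
    pick = rng.integers(0, k_neighbors, size=N)
    gaps = rng.random(N)
    neighbors = nn[seeds, pick]

    cat = np.array([c.is_categorical for c in split.columns])
    Xseed = split.S_m[seeds]
    Xnb = split.S_m[neighbors]
    Xs = Xseed + gaps[:, None] * (Xnb - Xseed)
    if cat.any():
        from_seed = gaps <= 0.5
        Xs[:, cat] = np.where(from_seed[:, None], Xseed[:, cat], Xnb[:, cat])
    return SyntheticBatch(Xs, seeds, neighbors, gaps)


def filter_candidates(batch: SyntheticBatch, split: ClassSplit) -> SyntheticBatch:
    """Keep candidates strictly closer to the minority set than the majority.

    A candidate is accepted iff min squared distance to any minority row is
    < the min squared distance to any majority row; equality rejects.  The
    relative order and provenance of survivors is preserved.
    """
    if len(batch) == 0:
        return batch
    enc = MixedEncoder(split.columns).fit(np.vstack([split.S_m, split.S_a]))
    E_c = enc.transform(batch.Xs)
    E_m = enc.transform(split.S_m)
    E_a = enc.transform(split.S_a)
    dmin_m = ((E_c[:, None, :] - E_m[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    dmin_a = ((E_c[:, None, :] - E_a[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    return batch.take(np.flatnonzero(dmin_m < dmin_a))


def _batch_majrap(batch: SyntheticBatch, split: ClassSplit) -> np.ndarray:
    enc = MixedEncoder(split.columns).fit(np.vstack([split.S_m, split.S_a]))
    E_c = enc.transform(batch.Xs)
    E_a = enc.transform(split.S_a)
    return ((E_c[:, None, :] - E_a[None, :, :]) ** 2).sum(axis=(1, 2))


def _batch_minrap(batch: SyntheticBatch, split: ClassSplit) -> np.ndarray:
    enc = MixedEncoder(split.columns).fit(np.vstack([split.S_m, split.S_a]))
    E_c = enc.transform(batch.Xs)
    E_m = enc.transform(split.S_m)
    return ((E_c[:, None, :] - E_m[None, :, :]) ** 2).sum(axis=(1, 2))


def denoise(
    accepted: SyntheticBatch,
    split: ClassSplit,
    mode: str = "closest",
) -> SyntheticBatch:
    """Remove floor(a/2) accepted candidates ranked by majority rapprochement.

    Default ``mode="closest"`` removes the candidates *closest* to the
    majority cloud (smallest ``maj_rap``); ties break toward the earlier
    candidate index.  ``mode="farthest"`` is the opposite reading and removes
    the largest.  Survivors are returned in their original order.
    """
    a = len(accepted)
    if a == 0:
        return accepted
    if mode not in ("closest", "farthest"):
        raise ValidationError(f"unknown denoise mode {mode!r}")
    rap = _batch_majrap(accepted, split)
    key = rap if mode == "closest" else -rap
    order = np.lexsort((accepted.index, key))
    removed = set(order[: a // 2].tolist())
    keep = np.array([i for i in range(a) if i not in removed], dtype=int)
    return accepted.take(keep)


def asmote_resample(
    d: Dataset,
    k_neighbors: int = 5,
    rng: np.random.Generator | int | None = None,
    denoise_mode: str = "closest",
) -> ResampleResult:
    """Full A-SMOTE pipeline on a two-class dataset.

    ``k_neighbors`` is clipped to z - 1 when the minority class is very
    small.  Original rows pass through bit-identically; retained candidates
    are appended with the minority label.  If no candidate survives
    filtering the original dataset is returned with a logged warning.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    split = class_split(d)
    if split.z < 2:
        raise TooFewMinorityError("A-SMOTE needs at least two minority samples")
    k = min(k_neighbors, split.z - 1)
    N = synth_count(split.r, split.z)

    batch = generate_candidates(split, N, k, rng)
    accepted = filter_candidates(batch, split)
    a = len(accepted)
    if a == 0:
        log.warning("A-SMOTE accepted 0 of %d candidates; dataset unchanged", N)
        return ResampleResult(
            augmented=d.copy(),
            n_requested=N,
            n_accepted=0,
            n_removed=0,
            accepted_majrap=np.empty(0),
            n_original_minority=split.z,
            n_original_majority=split.r,
        )

    L = float(_batch_minrap(accepted, split).sum())
    H = float(_batch_majrap(accepted, split).sum())
    kept = denoise(accepted, split, mode=denoise_mode)
    kept_rap = _batch_majrap(kept, split)
    log.info(
        "A-SMOTE: N=%d requested, a=%d accepted, %d removed, L=%.6g, H=%.6g",
        N, a, a // 2, L, H,
    )

    X_aug = np.vstack([d.X, kept.Xs])
    y_aug = np.concatenate([d.y, np.full(len(kept), split.minority_label, dtype=int)])
    augmented = Dataset(
        X=X_aug,
        y=y_aug,
        columns=list(d.columns),
        positive_label=d.positive_label,
        negative_label=d.negative_label,
        target_name=d.target_name,
    )
    return ResampleResult(
        augmented=augmented,
        n_requested=N,
        n_accepted=a,
        n_removed=a // 2,
        accepted_majrap=kept_rap,
        L=L,
        H=H,
        n_original_minority=split.z,
        n_original_majority=split.r,
    )
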