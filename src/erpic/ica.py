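"""Group ICA of averaged ERPs: decomposition, matching, spatial filtering.

ERPs of many subjects are concatenated along time and decomposed into
spatially fixed independent components (ICs).  Each IC is a pair of

* a *topography* — the mixing-matrix column, i.e. the scalp distribution of
  the underlying generator, normalized to unit L2 norm with the sign fixed
  so the topography is positive at its maximum-|value| channel; and
* a *spatial filter* — the unmixing-matrix row that projects a multichannel
  ERP onto the IC's activation curve.

Amplitude information lives entirely in the back-projected activation
curves ``topography[site] * (filter @ erp)``, which are in µV at the chosen
electrode site.  Decompositions computed on two cohorts can be compared by
dual correlation matching (topography and per-condition activation curves),
and the filters of one cohort can be applied, frozen, to ERPs of another —
the validation path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cohort import ERPCohort, SET_CONDITIONS
from .errors import DegenerateInputError, InvalidInputError, InvalidParameterError
from .montage import Montage

#: Components retained per preparatory set by default.
DEFAULT_N_ICS = {"continue": 8, "discontinue": 7}


# ---------------------------------------------------------------------------
# Preprocessing


def average_reference(erp: np.ndarray) -> np.ndarray:
    """Re-reference to the common average: subtract the per-sample channel mean.

    Idempotent projection onto the zero-mean subspace (rank channels - 1).
    """
    erp = np.asarray(erp, dtype=float)
    if erp.ndim != 2 or erp.shape[0] < 2:
        raise InvalidInputError("average reference requires >= 2 channels")
    return erp - erp.mean(axis=0, keepdims=True)


def grand_average(cohort: ERPCohort, condition: str, group: str = "all") -> np.ndarray:
    """Element-wise mean ERP across the selected subjects."""
    ci = cohort.condition_index(condition)
    if group == "all":
        sel = cohort.data[:, ci]
    else:
        mask = cohort.groups == group
        if not mask.any():
            raise InvalidInputError(f"no subjects selected for group {group!r}")
        sel = cohort.data[mask, ci]
    if sel.shape[0] == 0:
        raise InvalidInputError("empty subject selection")
    return sel.mean(axis=0)


@dataclass(frozen=True)
class StackedERP:
    """Subject-major concatenation of one preparatory set's ERPs."""

    matrix: np.ndarray  # channels x (n_subjects * 2 * n_samples)
    blocks: tuple[tuple[str, str, int, int], ...]  # (subject, condition, start, stop)
    set_id: str

    def block(self, subject_id: str, condition: str) -> np.ndarray:
        for sid, cond, a, b in self.blocks:
            if sid == subject_id and cond == condition:
                return self.matrix[:, a:b]
        raise InvalidInputError(f"no block for ({subject_id!r}, {condition!r})")


def stack_for_ica(cohort: ERPCohort, set_id: str) -> StackedERP:
    """Concatenate a cohort's ERPs of one preparatory set along time.

    Column blocks are ordered subject-major with the set's condition order
    within each subject (go, nogo for the continue set; ignore, novel for
    the discontinue set).
    """
    if set_id not in SET_CONDITIONS:
        raise InvalidInputError(f"unknown preparatory set {set_id!r}")
    conds = SET_CONDITIONS[set_id]
    for cond in conds:
        if cond not in cohort.conditions:
            raise InvalidInputError(f"cohort is missing condition {cond!r}")
    n = cohort.n_samples
    segments, blocks, pos = [], [], 0
    for subj in cohort.subjects:
        for cond in conds:
            segments.append(cohort.get(subj.id, cond))
            blocks.append((subj.id, cond, pos, pos + n))
            pos += n
    return StackedERP(np.concatenate(segments, axis=1), tuple(blocks), set_id)


def unstack(stacked: StackedERP) -> dict[tuple[str, str], np.ndarray]:
    """Inverse of :func:`stack_for_ica` (round-trip identity)."""
    return {
        (sid, cond): stacked.matrix[:, a:b] for sid, cond, a, b in stacked.blocks
    }


# ---------------------------------------------------------------------------
# Decomposition


@dataclass
class ICADecomposition:
    """A set of independent ERP components.

    ``filters @ topographies`` is the identity on the retained subspace;
    ``grand_activations[cond][i]`` is IC ``i``'s back-projected grand-average
    activation curve in µV at its site (``sites[i]``).
    """

    topographies: np.ndarray  # channels x n_ics, unit-norm columns
    filters: np.ndarray  # n_ics x channels
    grand_activations: dict[str, np.ndarray]  # condition -> n_ics x n_samples
    sites: np.ndarray  # per-IC channel index (max-|topography| channel)
    set_id: str
    montage: Montage
    ic_labels: tuple[str, ...] = ()
    seed: int | None = None
    exclusions: tuple[tuple[str, int, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.ic_labels:
            self.ic_labels = tuple(
                f"{self.set_id}-IC{i + 1}" for i in range(self.n_ics)
            )

    @property
    def n_ics(self) -> int:
        return self.topographies.shape[1]


def _normalize_polarity(
    topographies: np.ndarray, filters: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-norm topography columns, positive at the max-|value| channel.

    Filters are rescaled inversely so filters @ topographies is unchanged.
    """
    norms = np.linalg.norm(topographies, axis=0)
    if np.any(norms == 0):
        raise DegenerateInputError("zero topography column")
    peak = np.argmax(np.abs(topographies), axis=0)
    signs = np.sign(topographies[peak, np.arange(topographies.shape[1])])
    signs[signs == 0] = 1.0
    scale = norms * signs
    return topographies / scale, filters * scale[:, None]


def run_ica(
    stacked: StackedERP | np.ndarray,
    n_ics: int,
    seed: int = 0,
    grand_averages: dict[str, np.ndarray] | None = None,
    montage: Montage | None = None,
    set_id: str | None = None,
    algorithm: str = "fastica",
    max_iter: int = 1000,
) -> ICADecomposition:
    """Decompose stacked ERPs into ``n_ics`` independent components.

    The data are PCA-whitened to ``n_ics`` dimensions and unmixed by FastICA
    (default) or extended Infomax (``algorithm="infomax"``, via mne), both
    seeded and deterministic.  ``grand_averages`` (condition -> channels x
    samples) are projected through the filters and back-projected at each
    IC's site to fill ``grand_activations``.

    Raises
    ------
    DegenerateInputError
        If the data rank is below ``n_ics`` (the message names the rank).
    """
    if isinstance(stacked, StackedERP):
        X = stacked.matrix
        set_id = set_id or stacked.set_id
    else:
        X = np.asarray(stacked, dtype=float)
        set_id = set_id or "continue"
    n_ch, n_t = X.shape
    if n_ics > n_ch:
        raise InvalidParameterError(f"n_ics ({n_ics}) exceeds channels ({n_ch})")
    if n_t < n_ch:
        raise InvalidInputError("need at least as many samples as channels")

    Xc = X - X.mean(axis=1, keepdims=True)
    svals = np.linalg.svd(Xc, compute_uv=False)
    rank = int(np.sum(svals > svals[0] * 1e-10))
    if rank < n_ics:
        raise DegenerateInputError(
            f"input rank {rank} is below the requested {n_ics} components"
        )

    if algorithm == "fastica":
        from sklearn.decomposition import FastICA

        ica = FastICA(
            n_components=n_ics,
            whiten="unit-variance",
            max_iter=max_iter,
            tol=1e-6,
            random_state=seed,
        )
        ica.fit(X.T)
        filters = ica.components_  # n_ics x channels
    elif algorithm == "infomax":
        from mne.preprocessing import infomax

        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        K = (U[:, :n_ics] / s[:n_ics]).T * np.sqrt(n_t)  # whitening, n_ics x ch
        W = infomax(
            (K @ Xc).T, extended=True, random_state=seed, max_iter=max_iter,
            verbose=False,
        )
        filters = W @ K
    else:
        raise InvalidParameterError(f"unknown ICA algorithm {algorithm!r}")

    topographies = np.linalg.pinv(filters)  # channels x n_ics
    topographies, filters = _normalize_polarity(topographies, filters)
    sites = np.argmax(np.abs(topographies), axis=0)

    grand_acts: dict[str, np.ndarray] = {}
    if grand_averages:
        for cond, ga in grand_averages.items():
            acts = filters @ np.asarray(ga, dtype=float)
            grand_acts[cond] = topographies[sites, np.arange(n_ics)][:, None] * acts

    return ICADecomposition(
        topographies=topographies,
        filters=filters,
        grand_activations=grand_acts,
        sites=sites,
        set_id=set_id,
        montage=montage,  # type: ignore[arg-type]
        seed=seed,
    )


def decompose_cohort(
    cohort: ERPCohort,
    set_id: str,
    n_ics: int | None = None,
    seed: int = 0,
    algorithm: str = "fastica",
) -> ICADecomposition:
    """Stack a cohort's preparatory set, run ICA and fill grand activations."""
    n_ics = n_ics if n_ics is not None else DEFAULT_N_ICS[set_id]
    stacked = stack_for_ica(cohort, set_id)
    gas = {c: grand_average(cohort, c) for c in SET_CONDITIONS[set_id]}
    return run_ica(
        stacked, n_ics, seed=seed, grand_averages=gas,
        montage=cohort.montage, algorithm=algorithm,
    )


# ---------------------------------------------------------------------------
# Artifact exclusion


def exclude_artifact_ics(
    decomp: ICADecomposition,
    artifact_templates: Sequence[np.ndarray],
    r_threshold: float = 0.8,
) -> ICADecomposition:
    """Drop ICs whose topography matches any artifact template.

    A component is removed when |Pearson r| between its topography and a
    template reaches ``r_threshold``; removals are recorded in
    ``exclusions`` as (ic_label, template_index, r).
    """
    if not artifact_templates:
        return decomp
    removed: list[tuple[str, int, float]] = []
    keep = []
    for i in range(decomp.n_ics):
        topo = decomp.topographies[:, i]
        rs = [
            float(np.corrcoef(topo, np.asarray(t, dtype=float))[0, 1])
            for t in artifact_templates
        ]
        j = int(np.argmax(np.abs(rs)))
        if abs(rs[j]) >= r_threshold:
            removed.append((decomp.ic_labels[i], j, rs[j]))
        else:
            keep.append(i)
    keep_arr = np.array(keep, dtype=int)
    return replace(
        decomp,
        topographies=decomp.topographies[:, keep_arr],
        filters=decomp.filters[keep_arr],
        grand_activations={
            c: a[keep_arr] for c, a in decomp.grand_activations.items()
        },
        sites=decomp.sites[keep_arr],
        ic_labels=tuple(decomp.ic_labels[i] for i in keep),
        exclusions=decomp.exclusions + tuple(removed),
    )


# ---------------------------------------------------------------------------
# Cross-cohort matching


@dataclass(frozen=True)
class MatchCriteria:
    """Dual correlation admissibility rule for cross-cohort IC matching.

    A pair of ICs corresponds if topography correlation and the activation-
    curve correlation in *every* condition of the set all exceed their
    thresholds (default 0.5 each).
    """

    topo_r_min: float = 0.5
    curve_r_min: float = 0.5

    def __post_init__(self) -> None:
        for v in (self.topo_r_min, self.curve_r_min):
            if not 0 < v <= 1:
                raise InvalidParameterError("thresholds must lie in (0, 1]")


@dataclass(frozen=True)
class MatchedPair:
    index_a: int
    index_b: int
    r_topography: float
    r_curves: dict[str, float]  # per condition


@dataclass(frozen=True)
class MatchResult:
    pairs: tuple[MatchedPair, ...]
    unmatched_a: tuple[int, ...]
    unmatched_b: tuple[int, ...]


def _pearson_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Pearson r between columns of A and columns of B."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    denom = np.outer(
        np.linalg.norm(Ac, axis=0), np.linalg.norm(Bc, axis=0)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac.T @ Bc) / denom
    return np.nan_to_num(r)


def match_components(
    decomp_a: ICADecomposition,
    decomp_b: ICADecomposition,
    criteria: MatchCriteria = MatchCriteria(),
) -> MatchResult:
    """One-to-one matching of ICs between two decompositions.

    Among pairings restricted to admissible pairs (dual correlation rule),
    the total |topography correlation| is maximized; the assignment is
    solved exactly on a zero-padded weight matrix, so partial matchings are
    allowed and inadmissible pairs can never enter the result.
    """
    if decomp_a.set_id != decomp_b.set_id:
        raise InvalidInputError(
            f"set mismatch: {decomp_a.set_id!r} vs {decomp_b.set_id!r}"
        )
    if (
        decomp_a.montage is not None
        and decomp_b.montage is not None
        and decomp_a.montage.labels != decomp_b.montage.labels
    ):
        raise InvalidInputError("montage mismatch between decompositions")

    conds = SET_CONDITIONS[decomp_a.set_id]
    for d in (decomp_a, decomp_b):
        missing = [c for c in conds if c not in d.grand_activations]
        if missing:
            raise InvalidInputError(
                f"decomposition lacks grand activations for {missing}"
            )

    r_topo = _pearson_matrix(decomp_a.topographies, decomp_b.topographies)
    r_curve = {
        c: _pearson_matrix(
            decomp_a.grand_activations[c].T, decomp_b.grand_activations[c].T
        )
        for c in conds
    }
    admissible = r_topo > criteria.topo_r_min
    for c in conds:
        admissible &= r_curve[c] > criteria.curve_r_min

    na, nb = r_topo.shape
    n = max(na, nb)
    weight = np.zeros((n, n))
    weight[:na, :nb] = np.where(admissible, np.abs(r_topo), 0.0)
    rows, cols = linear_sum_assignment(weight, maximize=True)

    pairs = []
    for i, j in zip(rows, cols):
        if i < na and j < nb and admissible[i, j]:
            pairs.append(
                MatchedPair(
                    int(i), int(j), float(r_topo[i, j]),
                    {c: float(r_curve[c][i, j]) for c in conds},
                )
            )
    pairs.sort(key=lambda p: p.index_a)
    matched_a = {p.index_a for p in pairs}
    matched_b = {p.index_b for p in pairs}
    return MatchResult(
        tuple(pairs),
        tuple(i for i in range(na) if i not in matched_a),
        tuple(j for j in range(nb) if j not in matched_b),
    )


# ---------------------------------------------------------------------------
# Individual activation curves


def apply_spatial_filters(
    decomp: ICADecomposition, erp: np.ndarray, site: int | str | None = None
) -> np.ndarray:
    """Per-IC activation curves of one ERP, in µV at an electrode site.

    ``curve_i(t) = topography_i[site_i] * (filter_i @ erp)(t)``; linear in
    ``erp``.  With ``site=None`` each IC uses its own stored site; a channel
    label or index applies one common site to all ICs.
    """
    erp = np.asarray(erp, dtype=float)
    if erp.ndim != 2 or erp.shape[0] != decomp.filters.shape[1]:
        raise InvalidInputError(
            f"erp must be (channels={decomp.filters.shape[1]}, samples), "
            f"got {erp.shape}"
        )
    if site is None:
        sites = decomp.sites
    else:
        if isinstance(site, str):
            if decomp.montage is None:
                raise InvalidInputError("decomposition has no montage for label lookup")
            site = decomp.montage.index(site)
        if not 0 <= int(site) < erp.shape[0]:
            raise InvalidInputError(f"unknown site index {site}")
        sites = np.full(decomp.n_ics, int(site))
    acts = decomp.filters @ erp
    gains = decomp.topographies[sites, np.arange(decomp.n_ics)]
    return gains[:, None] * acts
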