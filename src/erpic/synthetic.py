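"""Synthetic ERP cohort generation with known ground truth.

The generator realizes the linear forward model that also underlies the ICA
stage: every scalp ERP is an instantaneous linear mixture of a small number
of sources, each with a spatially fixed topography and a condition-specific
activation curve,

    ERP(subject, condition) = A @ S(subject, condition) + noise,

where ``A`` (channels x sources) holds spatially smooth topographies and the
rows of ``S`` are sums of Gaussian-shaped deflections in the 100-500 ms
range.  A designated subset of sources carries a group effect (a latency
shift and/or an amplitude scaling applied to the case group), and subjects
add latency jitter and amplitude variability.  Because mixing matrix, source
curves and informative-source set are returned alongside the cohort, every
downstream stage (unmixing, matching, feature extraction, classification)
can be checked against planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .cohort import CONDITIONS, ERPCohort, N_SAMPLES, SAMPLING_RATE, Subject, times_ms
from .errors import InvalidParameterError
from .montage import Montage, standard_1020


class Deflection(NamedTuple):
    """One Gaussian-shaped ERP deflection.

    ``width_ms`` is the Gaussian standard deviation; the curve contribution is
    ``polarity * amplitude_uv * exp(-(t - latency_ms)^2 / (2 width_ms^2))``.
    """

    polarity: int  # +1 or -1
    latency_ms: float
    width_ms: float
    amplitude_uv: float


class GroupEffect(NamedTuple):
    """Latency shift (ms) and amplitude scale applied to the affected group."""

    latency_shift_ms: float = 0.0
    amplitude_scale: float = 1.0


@dataclass(frozen=True)
class SourceSpec:
    """Generative description of one ERP source.

    Parameters
    ----------
    name
        Human-readable source label.
    center
        Channel label at which the topography peaks.
    deflections
        Mapping condition -> list of :class:`Deflection`; conditions missing
        from the mapping have a zero activation curve.
    group_effect
        Latency shift / amplitude scaling applied to ``affected_group`` only.
    dominant_conditions
        Conditions in which the source is most active (used by downstream
        condition selection tests; informational for the generator).
    set_independent
        True for sources active in both preparatory sets (visual stream).
    smoothness
        Length scale (chord distance on the unit sphere) of the topography.
    """

    name: str
    center: str
    deflections: dict[str, tuple[Deflection, ...]]
    group_effect: GroupEffect = GroupEffect()
    affected_group: str = "case"
    dominant_conditions: frozenset[str] = frozenset()
    set_independent: bool = False
    smoothness: float = 0.6

    def __post_init__(self) -> None:
        if self.group_effect.amplitude_scale <= 0:
            raise InvalidParameterError("amplitude scale must be > 0")
        for cond, defls in self.deflections.items():
            if cond not in CONDITIONS:
                raise InvalidParameterError(f"unknown condition {cond!r}")
            for d in defls:
                if d.width_ms <= 0:
                    raise InvalidParameterError("deflection width must be > 0")
                if not 0 <= d.latency_ms <= 1000:
                    raise InvalidParameterError(
                        "peak latency must lie within [0, 1000] ms"
                    )

    @property
    def is_informative(self) -> bool:
        return self.group_effect != GroupEffect()


@dataclass(frozen=True)
class CohortParams:
    """Study-condition parameters of a simulated cohort."""

    n_per_group: int = 50
    n_sources: int = 8
    noise_sd: float = 1.0  # µV, additive sensor noise on averaged ERPs
    subject_latency_jitter_sd: float = 8.0  # ms
    subject_amplitude_sd: float = 0.2  # fractional
    sampling_rate: float = SAMPLING_RATE
    epoch_ms: tuple[float, float] = (0.0, 1000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise InvalidParameterError("n_per_group must be >= 2")
        if self.noise_sd < 0 or self.subject_latency_jitter_sd < 0:
            raise InvalidParameterError("noise and jitter sds must be >= 0")
        n = (self.epoch_ms[1] - self.epoch_ms[0]) / 1000.0 * self.sampling_rate
        if round(n) != N_SAMPLES:
            raise InvalidParameterError(
                f"epoch/sampling rate must yield {N_SAMPLES} samples, got {n:g}"
            )


@dataclass
class GroundTruth:
    """Planted quantities of a simulated cohort.

    ``source_curves`` has shape (n_subjects, n_conditions, n_sources,
    n_samples) in µV; ``informative`` indexes sources carrying a group effect.
    """

    mixing: np.ndarray  # channels x sources, unit-norm columns
    source_curves: np.ndarray = field(repr=False)
    informative: tuple[int, ...] = ()
    source_names: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Topographies


def make_topographies(
    montage: Montage,
    n_sources: int,
    smoothness: float = 0.6,
    seed: int = 0,
    centers: Sequence[str] | None = None,
    max_pair_corr: float = 0.95,
) -> np.ndarray:
    """Spatially smooth random topographies (mixing-matrix columns).

    Columns are draws from a Gaussian process on the electrode positions with
    squared-exponential covariance of length scale ``smoothness`` (chord
    distance).  If ``centers`` is given, each column additionally carries a
    deterministic bump peaking at the named channel, emulating a focal
    generator.  Columns are unit L2 norm; draws violating the pairwise
    correlation bound are rejected and resampled.
    """
    if n_sources > montage.n_channels:
        raise InvalidParameterError(
            f"n_sources ({n_sources}) exceeds channel count ({montage.n_channels})"
        )
    if centers is not None and len(centers) != n_sources:
        raise InvalidParameterError("centers must have one entry per source")
    rng = np.random.default_rng(seed)
    d = montage.distances()
    cov = np.exp(-(d ** 2) / (2.0 * smoothness ** 2))
    chol = np.linalg.cholesky(cov + 1e-9 * np.eye(montage.n_channels))

    cols: list[np.ndarray] = []
    for j in range(n_sources):
        for _ in range(200):
            topo = chol @ rng.standard_normal(montage.n_channels)
            if centers is not None:
                ci = montage.index(centers[j])
                bump = np.exp(-(d[ci] ** 2) / (2.0 * smoothness ** 2))
                topo = bump + 0.3 * topo
            topo = topo / np.linalg.norm(topo)
            if not cols:
                break
            r = [abs(np.corrcoef(topo, c)[0, 1]) for c in cols]
            if max(r) < max_pair_corr:
                break
        else:  # pragma: no cover - astronomically unlikely with random fields
            raise InvalidParameterError(
                "could not draw topographies satisfying the correlation bound"
            )
        cols.append(topo)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Activation curves


def make_activation(
    spec: SourceSpec,
    condition: str,
    group: str,
    subject_jitter: tuple[float, float] = (0.0, 1.0),
) -> np.ndarray:
    """Activation curve (µV, 250 samples) of one source in one condition.

    The curve is a sum of Gaussian deflections; the source's group effect is
    applied only when ``group`` equals the spec's affected group.
    ``subject_jitter`` is an additive latency offset (ms) and a multiplicative
    amplitude factor shared by all deflections of this subject/source.
    """
    if condition not in CONDITIONS:
        raise InvalidParameterError(f"unknown condition {condition!r}")
    t = times_ms()
    curve = np.zeros(N_SAMPLES)
    dt, scale = subject_jitter
    if group == spec.affected_group:
        dt = dt + spec.group_effect.latency_shift_ms
        scale = scale * spec.group_effect.amplitude_scale
    for d in spec.deflections.get(condition, ()):  # empty list -> zero curve
        lat = d.latency_ms + dt
        curve += (
            d.polarity
            * d.amplitude_uv
            * scale
            * np.exp(-((t - lat) ** 2) / (2.0 * d.width_ms ** 2))
        )
    return curve


# ---------------------------------------------------------------------------
# Cohorts


def simulate_cohort(
    params: CohortParams,
    specs: Sequence[SourceSpec],
    montage: Montage | None = None,
    average_ref: bool = False,
    group_sizes: dict[str, int] | None = None,
    mixing: np.ndarray | None = None,
) -> tuple[ERPCohort, GroundTruth]:
    """Simulate a cohort of averaged ERPs with known ground truth.

    Each subject/condition ERP is ``mixing @ sources + N(0, noise_sd)``.
    Subjects draw one latency offset ~ N(0, jitter_sd) and one amplitude
    factor ~ N(1, amplitude_sd) per source, shared across conditions (a
    stable individual trait).  With ``group_sizes`` the default balanced
    design (``n_per_group`` controls + cases) can be overridden, e.g.
    ``{"case": 17}`` for an all-case validation sample, and ``mixing`` lets
    a second cohort reuse the planted topographies of an earlier one (same
    generators, new subjects).
    """
    montage = montage or standard_1020()
    if len(specs) != params.n_sources:
        raise InvalidParameterError(
            f"expected {params.n_sources} source specs, got {len(specs)}"
        )
    if params.n_sources > montage.n_channels:
        raise InvalidParameterError("n_sources exceeds channel count")

    rng = np.random.default_rng(params.seed)
    if mixing is None:
        mixing = make_topographies(
            montage,
            params.n_sources,
            smoothness=float(np.mean([s.smoothness for s in specs])),
            seed=params.seed,
            centers=[s.center for s in specs],
        )
    else:
        mixing = np.asarray(mixing, dtype=float)
        if mixing.shape != (montage.n_channels, params.n_sources):
            raise InvalidParameterError(
                f"mixing must be ({montage.n_channels}, {params.n_sources})"
            )
    if np.linalg.matrix_rank(mixing) < params.n_sources:  # pragma: no cover
        raise InvalidParameterError("mixing matrix is rank deficient")

    if group_sizes is None:
        group_sizes = {"control": params.n_per_group, "case": params.n_per_group}
    subjects = [
        Subject(f"{grp}{i + 1:03d}", grp)
        for grp in ("control", "case")
        for i in range(group_sizes.get(grp, 0))
    ]

    n_subj = len(subjects)
    n_src = params.n_sources
    data = np.empty((n_subj, len(CONDITIONS), montage.n_channels, N_SAMPLES))
    curves = np.empty((n_subj, len(CONDITIONS), n_src, N_SAMPLES))
    for si, subj in enumerate(subjects):
        jit_dt = rng.normal(0.0, params.subject_latency_jitter_sd, n_src)
        jit_scale = np.clip(
            rng.normal(1.0, params.subject_amplitude_sd, n_src), 0.1, None
        )
        for ci, cond in enumerate(CONDITIONS):
            for k, spec in enumerate(specs):
                curves[si, ci, k] = make_activation(
                    spec, cond, subj.group, (jit_dt[k], jit_scale[k])
                )
            erp = mixing @ curves[si, ci]
            if params.noise_sd > 0:
                erp = erp + rng.normal(
                    0.0, params.noise_sd, (montage.n_channels, N_SAMPLES)
                )
            data[si, ci] = erp

    if average_ref:
        data = data - data.mean(axis=2, keepdims=True)

    cohort = ERPCohort(subjects, data, montage, params.sampling_rate)
    truth = GroundTruth(
        mixing=mixing,
        source_curves=curves,
        informative=tuple(i for i, s in enumerate(specs) if s.is_informative),
        source_names=tuple(s.name for s in specs),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Default source catalogue


def default_sources(
    latency_shift_ms: float = 40.0, amplitude_scale: float = 1.5
) -> list[SourceSpec]:
    """Default 8-source catalogue emulating a go/no-go ERP component set.

    Five sources are active in the continue set (go/nogo), four in the
    discontinue set (ignore/novel), one of them in all conditions (early
    visual stream).  Sources 1 (inhibition-related N2/P3 sequence, nogo),
    2 (parietal P3b, go) and 5 (novelty P3a) carry the group effect: cases
    peak ``latency_shift_ms`` later with amplitudes scaled by
    ``amplitude_scale``.
    """
    eff = GroupEffect(latency_shift_ms, amplitude_scale)
    vis = (Deflection(-1, 145, 22, 4.0), Deflection(+1, 235, 30, 4.0))
    return [
        SourceSpec(
            "visual-occipital", "O1",
            {c: vis for c in CONDITIONS},
            dominant_conditions=frozenset(CONDITIONS),
            set_independent=True,
        ),
        SourceSpec(
            "n2-nogo-frontal", "Fz",
            {
                "nogo": (Deflection(-1, 270, 28, 6.0), Deflection(+1, 400, 38, 5.0)),
                "go": (Deflection(-1, 270, 28, 2.0),),
            },
            group_effect=eff,
            dominant_conditions=frozenset({"nogo"}),
        ),
        SourceSpec(
            "p3b-go-parietal", "Pz",
            {
                "go": (Deflection(+1, 355, 42, 7.0),),
                "nogo": (Deflection(+1, 355, 42, 2.5),),
            },
            group_effect=eff,
            dominant_conditions=frozenset({"go"}),
        ),
        SourceSpec(
            "premotor-go-nogo", "C3",
            {
                "go": (Deflection(-1, 190, 22, 2.5), Deflection(+1, 315, 26, 5.0)),
                "nogo": (Deflection(-1, 140, 22, 2.5), Deflection(+1, 255, 26, 5.0)),
            },
            dominant_conditions=frozenset({"go", "nogo"}),
        ),
        SourceSpec(
            "sma-nogo", "Cz",
            {
                "nogo": (
                    Deflection(+1, 195, 24, 3.0),
                    Deflection(+1, 345, 30, 6.0),
                    Deflection(+1, 505, 32, 3.0),
                ),
                "go": (Deflection(+1, 345, 30, 2.0),),
            },
            dominant_conditions=frozenset({"nogo"}),
        ),
        SourceSpec(
            "p3a-novelty", "F4",
            {
                "novel": (Deflection(+1, 330, 40, 7.0),),
                "ignore": (Deflection(+1, 330, 40, 2.0),),
            },
            group_effect=eff,
            dominant_conditions=frozenset({"novel"}),
        ),
        SourceSpec(
            "auditory-n1-novelty", "T4",
            {
                "novel": (
                    Deflection(-1, 118, 20, 5.0),
                    Deflection(+1, 205, 24, 3.0),
                    Deflection(+1, 435, 34, 4.0),
                ),
                "ignore": (
                    Deflection(-1, 118, 20, 1.5),
                    Deflection(+1, 205, 24, 1.0),
                ),
            },
            dominant_conditions=frozenset({"novel"}),
        ),
        SourceSpec(
            "occipito-temporal-ignore", "T6",
            {
                "ignore": (
                    Deflection(+1, 118, 18, 3.0),
                    Deflection(-1, 172, 20, 5.0),
                    Deflection(+1, 290, 28, 4.0),
                ),
                "novel": (
                    Deflection(+1, 118, 18, 2.7),
                    Deflection(-1, 172, 20, 4.5),
                    Deflection(+1, 290, 28, 3.6),
                ),
            },
            dominant_conditions=frozenset({"ignore", "novel"}),
        ),
    ]
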