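"""Window-grid latency/amplitude features from IC activation curves.

A feature template sweeps closed time windows over each selected activation
curve: window starts advance in 8 ms steps from 0 ms, window widths are a
base width of 114 ms scaled by {0.5, 0.75, 1, 1.25, 1.5} and floored to the
4 ms sample grid (56, 84, 112, 140, 168 ms), and windows must end by 700 ms.
Within each window five feature kinds are computed: the minimum and maximum
peak amplitude (window extrema, µV), their latencies (ms, earliest sample on
ties), and the mean amplitude.  One feature column is produced per
(IC, condition, window, kind).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import SAMPLE_STEP_MS
from .errors import InvalidInputError, InvalidParameterError

#: Canonical feature kinds.
KINDS: tuple[str, ...] = (
    "min_peak_latency",
    "max_peak_latency",
    "min_peak_amplitude",
    "max_peak_amplitude",
    "mean_amplitude",
)

LATENCY_KINDS = frozenset({"min_peak_latency", "max_peak_latency"})


@dataclass(frozen=True)
class FeatureTemplate:
    """The window-grid feature grammar.

    Defaults reproduce the published template: curves considered from 0 to
    700 ms, window starts every 8 ms, base width 114 ms with ±25% and ±50%
    scalings, five feature kinds.
    """

    start_ms: float = 0.0
    end_ms: float = 700.0
    step_ms: float = 8.0
    base_width_ms: float = 114.0
    width_scales: tuple[float, ...] = (0.5, 0.75, 1.0, 1.25, 1.5)
    kinds: tuple[str, ...] = KINDS

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise InvalidParameterError("template start must precede end")
        if self.step_ms <= 0 or self.step_ms % SAMPLE_STEP_MS:
            raise InvalidParameterError(
                f"step must be a positive multiple of {SAMPLE_STEP_MS:g} ms"
            )
        unknown = set(self.kinds) - set(KINDS)
        if unknown:
            raise InvalidParameterError(f"unknown feature kinds {sorted(unknown)}")
        for w in self.widths_ms():
            if w < 2 * SAMPLE_STEP_MS:
                raise InvalidParameterError(
                    f"window width {w:g} ms spans fewer than 2 samples"
                )

    def widths_ms(self) -> tuple[float, ...]:
        """Window widths: base x scales, floored to the sample grid."""
        return tuple(
            float(np.floor(self.base_width_ms * s / SAMPLE_STEP_MS) * SAMPLE_STEP_MS)
            for s in self.width_scales
        )


def enumerate_windows(template: FeatureTemplate) -> list[tuple[float, float]]:
    """All closed windows [start, start + width] of the template's grid.

    Starts advance from ``start_ms`` in ``step_ms`` increments while the
    window still ends by ``end_ms``.  For the defaults this yields
    81 + 78 + 74 + 71 + 67 = 371 windows.
    """
    windows: list[tuple[float, float]] = []
    for width in template.widths_ms():
        start = template.start_ms
        while start + width <= template.end_ms + 1e-9:
            windows.append((float(start), float(start + width)))
            start += template.step_ms
    return windows


@dataclass(frozen=True)
class FeatureSpec:
    """Identity of one feature column: IC, condition, window, kind."""

    ic_label: str
    condition: str
    window: tuple[float, float]  # [start, end] ms, closed
    kind: str

    @property
    def key(self) -> str:
        a, b = self.window
        return f"{self.ic_label}|{self.condition}|{a:g}-{b:g}|{self.kind}"

    @classmethod
    def from_key(cls, key: str) -> "FeatureSpec":
        ic, cond, win, kind = key.split("|")
        a, b = win.split("-")
        return cls(ic, cond, (float(a), float(b)), kind)


def _window_samples(window: tuple[float, float], n_samples: int) -> tuple[int, int]:
    a, b = window
    ia = int(round(a / SAMPLE_STEP_MS))
    ib = int(round(b / SAMPLE_STEP_MS))
    if ia < 0 or ib >= n_samples or ia > ib:
        raise InvalidInputError(
            f"window [{a:g}, {b:g}] ms outside the curve span "
            f"[0, {(n_samples - 1) * SAMPLE_STEP_MS:g}] ms"
        )
    return ia, ib


def extract_feature(
    curve: np.ndarray, window: tuple[float, float], kind: str
) -> float:
    """One feature value from one activation curve.

    Peaks are window extrema over the samples inside the closed window;
    latencies are the extremum's time in ms (earliest sample on ties).
    """
    curve = np.asarray(curve, dtype=float)
    if kind not in KINDS:
        raise InvalidParameterError(f"unknown feature kind {kind!r}")
    ia, ib = _window_samples(window, curve.shape[-1])
    seg = curve[ia : ib + 1]
    if kind == "mean_amplitude":
        return float(seg.mean())
    if kind == "min_peak_amplitude":
        return float(seg.min())
    if kind == "max_peak_amplitude":
        return float(seg.max())
    idx = int(np.argmin(seg)) if kind == "min_peak_latency" else int(np.argmax(seg))
    return float((ia + idx) * SAMPLE_STEP_MS)


# ---------------------------------------------------------------------------
# Site and condition selection


def select_site(
    topography: np.ndarray, activation_curves: Iterable[np.ndarray]
) -> int:
    """Channel with the most distinct back-projected grand-average amplitude.

    For each channel ``c`` the peak |amplitude| of the back-projection
    ``topography[c] * activation(t)`` is evaluated over all supplied curves;
    the argmax channel is returned, ties broken by montage order.
    """
    topo = np.asarray(topography, dtype=float)
    peak = max(
        (float(np.max(np.abs(np.asarray(a, dtype=float)))) for a in activation_curves),
        default=0.0,
    )
    per_channel = np.abs(topo) * peak
    return int(np.argmax(per_channel))  # argmax returns the first maximum


def select_conditions(
    grand_activations: Mapping[str, np.ndarray],
    ratio_threshold: float = 0.8,
    force_ignore: bool = False,
) -> tuple[str, ...]:
    """Conditions whose activation curves enter feature extraction.

    The dominant condition is the one with the larger peak-to-peak
    grand-average amplitude; another condition is also included iff its
    peak-to-peak reaches ``ratio_threshold`` times the dominant one.
    Preparatory-set-independent ICs are forced to the ignore condition.
    """
    if force_ignore:
        return ("ignore",)
    if not grand_activations:
        raise InvalidInputError("need at least one condition curve")
    conds = list(grand_activations)
    ptp = {c: float(np.ptp(np.asarray(grand_activations[c], dtype=float))) for c in conds}
    dominant = max(conds, key=lambda c: (ptp[c], -conds.index(c)))
    selected = [
        c for c in conds
        if c == dominant or ptp[c] >= ratio_threshold * ptp[dominant]
    ]
    return tuple(selected)


# ---------------------------------------------------------------------------
# Feature matrix


@dataclass
class CohortActivations:
    """Individual IC activation curves entering feature extraction.

    ``curves`` has shape (n_subjects, n_entries, n_samples) in µV at each
    IC's site; ``entries[k]`` names the (ic_label, condition) of column k.
    """

    subject_ids: list[str]
    groups: np.ndarray
    entries: list[tuple[str, str]]
    curves: np.ndarray = field(repr=False)


@dataclass
class FeatureMatrix:
    """Subjects x named features, the classifier's input."""

    values: pd.DataFrame  # index: subject ids, columns: FeatureSpec keys
    groups: pd.Series  # index: subject ids, values in {case, control}

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.groups.index):
            raise InvalidInputError("feature rows and group labels must align")
        if self.values.columns.duplicated().any():
            raise InvalidInputError("feature column keys must be unique")
        if self.values.isna().any().any():
            raise InvalidInputError("feature matrix contains missing values")

    @property
    def specs(self) -> list[FeatureSpec]:
        return [FeatureSpec.from_key(k) for k in self.values.columns]

    def subset(self, keys: Sequence[str]) -> "FeatureMatrix":
        missing = [k for k in keys if k not in self.values.columns]
        if missing:
            raise InvalidInputError(f"missing feature keys: {missing}")
        return FeatureMatrix(self.values.loc[:, list(keys)], self.groups)


def build_feature_matrix(
    activations: CohortActivations, template: FeatureTemplate
) -> FeatureMatrix:
    """Evaluate the full window grid on every selected activation curve.

    Columns are ordered entry-major, then window (width ascending, start
    ascending), then kind; the column key encodes the FeatureSpec.  The
    extraction is vectorized over subjects and windows but is numerically
    identical to calling :func:`extract_feature` per cell.
    """
    curves = np.asarray(activations.curves, dtype=float)
    n_subj, n_entries, n_samples = curves.shape
    if n_subj != len(activations.subject_ids):
        raise InvalidInputError("curves and subject ids disagree")
    bad = np.argwhere(~np.isfinite(curves))
    if bad.size:
        raise InvalidInputError(
            f"non-finite activation curve for subject "
            f"{activations.subject_ids[bad[0][0]]!r}"
        )

    windows = enumerate_windows(template)
    step_samp = int(round(template.step_ms / SAMPLE_STEP_MS))
    columns: dict[str, np.ndarray] = {}
    for e, (ic_label, cond) in enumerate(activations.entries):
        ent = curves[:, e, :]
        for width in template.widths_ms():
            w_samp = int(round(width / SAMPLE_STEP_MS))
            starts = [w for w in windows if w[1] - w[0] == width]
            ia0 = int(round(template.start_ms / SAMPLE_STEP_MS))
            view = np.lib.stride_tricks.sliding_window_view(
                ent, w_samp + 1, axis=1
            )[:, ia0 :: step_samp][:, : len(starts)]
            mins = view.min(axis=2)
            maxs = view.max(axis=2)
            argmins = view.argmin(axis=2)
            argmaxs = view.argmax(axis=2)
            means = view.mean(axis=2)
            start_samples = np.array(
                [int(round(a / SAMPLE_STEP_MS)) for a, _ in starts]
            )
            values_by_kind = {
                "min_peak_latency": (start_samples + argmins) * SAMPLE_STEP_MS,
                "max_peak_latency": (start_samples + argmaxs) * SAMPLE_STEP_MS,
                "min_peak_amplitude": mins,
                "max_peak_amplitude": maxs,
                "mean_amplitude": means,
            }
            for wi, window in enumerate(starts):
                for kind in template.kinds:
                    spec = FeatureSpec(ic_label, cond, window, kind)
                    columns[spec.key] = values_by_kind[kind][:, wi]

    df = pd.DataFrame(columns, index=pd.Index(activations.subject_ids, name="subject"))
    groups = pd.Series(
        activations.groups, index=df.index, name="group"
    )
    return FeatureMatrix(df, groups)
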