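"""Stress-strain analysis of ring tensile tests.

A ring pulled over two gripper pins carries load through two tissue limbs,
so engineering stress is N/(2*A0) with A0 the elliptical cross-sectional
area of one limb.  Engineering strain references the gauge length recorded
when the raw load first exceeds the tension-onset threshold (5 mN).  True
stress and strain assume volume conservation and uniform deformation:

    eps_true = ln(1 + eps_eng)        sigma_true = sigma_eng * (1 + eps_eng)

The stiffness endpoint is the maximum tangent modulus (MTM): the largest
ordinary-least-squares slope of stress on strain over every window of 8%
strain width anchored at each sample.  The failure event is the first drop
in load exceeding 40% of the running maximum, the instrument's termination
criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .traceio import TensileTrace, TestProtocol

__all__ = [
    "StressStrainCurve",
    "MechanicalSummary",
    "TangentWindow",
    "subtract_drag",
    "detect_tension_onset",
    "elliptical_area",
    "to_stress_strain",
    "tangent_modulus_profile",
    "detect_failure",
    "summarize",
    "analyze_trace",
    "TENSION_ONSET_THRESHOLD_N",
    "MTM_WINDOW_STRAIN",
]

#: raw-load threshold defining tension onset (5 mN, in N)
TENSION_ONSET_THRESHOLD_N = 0.005
#: strain width of the sliding tangent-modulus window
MTM_WINDOW_STRAIN = 0.08


class NeverInTensionError(ValueError):
    """No sample of the raw load exceeds the tension-onset threshold."""


class CurveTooShortError(ValueError):
    """The strain span is smaller than the tangent-modulus window."""


@dataclass
class StressStrainCurve:
    """Paired engineering and true stress-strain arrays for one specimen.

    Arrays start at the tension-onset sample (eng_strain[0] == 0).  Stress
    is in MPa, strain dimensionless.  ``onset_index`` points back into the
    source trace.
    """

    eng_strain: np.ndarray
    eng_stress: np.ndarray
    gauge_length: float  # mm
    a0: float  # mm^2
    area_convention: str = "minimum"
    onset_index: int = 0

    def __post_init__(self) -> None:
        self.eng_strain = np.asarray(self.eng_strain, dtype=float)
        self.eng_stress = np.asarray(self.eng_stress, dtype=float)
        if self.a0 <= 0:
            raise ValueError(f"a0 must be positive, got {self.a0}")
        if self.gauge_length <= 0:
            raise ValueError(f"gauge_length must be positive, got {self.gauge_length}")
        if len(self.eng_strain) != len(self.eng_stress):
            raise ValueError("strain/stress length mismatch")
        if self.eng_strain[0] != 0.0:
            raise ValueError("eng_strain must start at 0 at the onset sample")
        if np.any(np.diff(self.eng_strain) < 0):
            raise ValueError("eng_strain must be non-decreasing")

    @property
    def true_strain(self) -> np.ndarray:
        return np.log1p(self.eng_strain)

    @property
    def true_stress(self) -> np.ndarray:
        return self.eng_stress * (1.0 + self.eng_strain)

    def strain(self, convention: str = "engineering") -> np.ndarray:
        return self.true_strain if convention == "true" else self.eng_strain

    def stress(self, convention: str = "engineering") -> np.ndarray:
        return self.true_stress if convention == "true" else self.eng_stress

    def __len__(self) -> int:
        return len(self.eng_strain)


@dataclass
class TangentWindow:
    """One sliding-window OLS fit: slope of stress on strain in MPa."""

    start_index: int
    end_index: int  # inclusive index of the last sample in the window
    start_strain: float
    slope: float


@dataclass
class MechanicalSummary:
    """The three tensile endpoints for one specimen."""

    uts: float  # MPa
    mtm: float  # MPa
    failure_strain: float  # strain at the detected termination sample
    strain_at_uts: float
    mtm_window_start_strain: float
    failure_detected: bool
    stress_convention: str = "engineering"

    def __post_init__(self) -> None:
        if self.uts < 0 or self.mtm < 0:
            raise ValueError("uts and mtm must be non-negative")


def subtract_drag(trace: TensileTrace, baseline: TensileTrace) -> TensileTrace:
    """Remove the gripper drag force measured with no specimen loaded.

    The baseline load is linearly interpolated at the trace's extensions and
    subtracted.  The baseline must cover at least 90% of the trace's
    extension range; the remainder is extrapolated by edge-value clamping.
    """
    if not baseline.is_baseline:
        raise ValueError("baseline trace must have is_baseline=True")
    span = trace.extension[-1] - trace.extension[0]
    if span > 0:
        lo = max(trace.extension[0], baseline.extension[0])
        hi = min(trace.extension[-1], baseline.extension[-1])
        coverage = max(0.0, hi - lo) / span
        if coverage < 0.90:
            raise ValueError(
                f"baseline covers only {coverage:.0%} of the trace extension range"
            )
    drag = np.interp(trace.extension, baseline.extension, baseline.load)
    return trace.replace(load=trace.load - drag)


def detect_tension_onset(
    trace: TensileTrace,
    protocol: TestProtocol,
    threshold: float = TENSION_ONSET_THRESHOLD_N,
) -> tuple[int, float]:
    """Find the tension-onset sample and record the gauge length.

    The specimen is considered in tension at the first sample whose *raw*
    (pre-drag-subtraction) load exceeds ``threshold`` (default 5 mN).  The
    gauge length is the grip-to-grip distance at that moment:
    ``initial_grip_distance + extension[onset]``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    above = np.flatnonzero(trace.load > threshold)
    if above.size == 0:
        raise NeverInTensionError(
            f"no sample exceeds the {threshold * 1000:.1f} mN tension threshold"
        )
    onset = int(above[0])
    gauge_length = protocol.initial_grip_distance + float(trace.extension[onset])
    return onset, gauge_length


def elliptical_area(width: float, height: float) -> float:
    """Elliptical cross-sectional area pi*(w/2)*(h/2), mm^2."""
    if width <= 0 or height <= 0:
        raise ValueError(f"dimensions must be positive, got {width} x {height}")
    return math.pi * (width / 2.0) * (height / 2.0)


def to_stress_strain(
    trace: TensileTrace,
    onset_index: int,
    gauge_length: float,
    a0: float,
    area_convention: str = "minimum",
) -> StressStrainCurve:
    """Convert a drag-corrected trace to a stress-strain curve.

    Strain references the extension at onset (dL = extension - extension[onset])
    over the gauge length; stress divides the load by 2*a0 for the ring's two
    load-bearing limbs.  Loads in N over areas in mm^2 give MPa directly.
    """
    if not 0 <= onset_index < len(trace):
        raise ValueError(f"onset_index {onset_index} outside trace of {len(trace)}")
    if gauge_length <= 0:
        raise ValueError("gauge_length must be positive")
    if a0 <= 0:
        raise ValueError("a0 must be positive")
    ext = trace.extension[onset_index:]
    load = trace.load[onset_index:]
    eng_strain = (ext - ext[0]) / gauge_length
    eng_stress = load / (2.0 * a0)
    return StressStrainCurve(
        eng_strain=eng_strain,
        eng_stress=eng_stress,
        gauge_length=gauge_length,
        a0=a0,
        area_convention=area_convention,
        onset_index=onset_index,
    )


def tangent_modulus_profile(
    curve: StressStrainCurve,
    window_strain: float = MTM_WINDOW_STRAIN,
    stress_convention: str = "engineering",
    strain_convention: str | None = None,
) -> list[TangentWindow]:
    """OLS slope of stress on strain over every window of ``window_strain`` width.

    A window anchored at sample i spans all samples with strain in
    [strain[i], strain[i] + window_strain]; only windows that fit entirely
    inside the curve and contain >= 3 samples are reported.  Slopes are in
    MPa.  By default both axes use the engineering convention;
    ``strain_convention`` may be set independently of the stress axis.
    """
    if strain_convention is None:
        strain_convention = stress_convention
    x = curve.strain(strain_convention)
    y = curve.stress(stress_convention)
    span = x[-1] - x[0]
    if span < window_strain:
        raise CurveTooShortError(
            f"strain span {span:.4f} is shorter than the {window_strain:.2f} window"
        )
    # right-inclusive window ends, vectorized via cumulative sums
    ends = np.searchsorted(x, x + window_strain, side="right") - 1
    n = len(x)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(y)])
    c3 = np.concatenate([[0.0], np.cumsum(x * y)])
    c4 = np.concatenate([[0.0], np.cumsum(x * x)])
    windows: list[TangentWindow] = []
    for i in range(n):
        j = ends[i]
        if j >= n or x[i] + window_strain > x[-1] + 1e-15:
            break
        m = j - i + 1
        if m < 3:
            continue
        sx = c1[j + 1] - c1[i]
        sy = c2[j + 1] - c2[i]
        sxy = c3[j + 1] - c3[i]
        sxx = c4[j + 1] - c4[i]
        denom = m * sxx - sx * sx
        if denom <= 0:
            continue
        slope = (m * sxy - sx * sy) / denom
        windows.append(TangentWindow(i, int(j), float(x[i]), float(slope)))
    if not windows:
        raise CurveTooShortError("no window with >= 3 samples fits the curve")
    return windows


def detect_failure(
    loads: np.ndarray,
    drop_fraction: float = 0.40,
    min_peak_fraction: float = 0.20,
    confirm: bool = True,
) -> tuple[int, bool]:
    """First sample whose load falls below (1 - drop_fraction) of the running max.

    Mirrors the instrument's termination rule, hardened for offline use on
    noisy records: the rule is only armed once the running maximum reaches
    ``min_peak_fraction`` of the record's overall peak (so the pre-tension
    noise floor cannot trigger it), and with ``confirm`` a candidate drop
    must be sustained — the next sample, if one exists, must also sit below
    the threshold.  If no drop qualifies the last sample is returned with
    ``failure_detected=False``.  ``loads`` may be a load or stress array
    (the rule is scale-invariant).
    """
    loads = np.asarray(loads, dtype=float)
    if len(loads) < 2:
        raise ValueError("need >= 2 samples")
    running_max = np.maximum.accumulate(loads)
    floor = min_peak_fraction * loads.max()
    threshold = (1.0 - drop_fraction) * running_max
    candidates = np.flatnonzero((loads < threshold) & (running_max >= floor))
    for idx in candidates:
        idx = int(idx)
        if not confirm or idx == len(loads) - 1 or loads[idx + 1] < threshold[idx]:
            return idx, True
    return len(loads) - 1, False


def summarize(
    curve: StressStrainCurve,
    profile: list[TangentWindow],
    failure_index: int,
    failure_detected: bool = True,
    stress_convention: str = "engineering",
    peak_median_window: int = 5,
) -> MechanicalSummary:
    """Collapse a curve and its tangent profile to UTS, MTM and failure strain.

    UTS is the peak stress at or before the failure sample, taken from a
    short rolling-median of the stress (``peak_median_window`` samples,
    1 disables) so a single noisy load-cell sample cannot define the peak.
    MTM considers only windows ending at or before the failure sample.
    Failure strain is the strain at the detected termination sample; the
    strain at peak stress is reported alongside.  Ties in the maximum slope
    resolve to the earliest window.
    """
    if not profile:
        raise ValueError("empty tangent-modulus profile")
    if not 0 <= failure_index < len(curve):
        raise ValueError(f"failure_index {failure_index} outside curve")
    eligible = [w for w in profile if w.end_index <= failure_index]
    if not eligible:
        raise ValueError("failure occurs before the first full tangent window")
    best = max(eligible, key=lambda w: (w.slope, -w.start_index))
    stress = curve.stress(stress_convention)[: failure_index + 1]
    strain = curve.strain(stress_convention)[: failure_index + 1]
    if peak_median_window > 1 and len(stress) >= peak_median_window:
        smoothed = median_filter(stress, size=peak_median_window, mode="nearest")
    else:
        smoothed = stress
    peak = int(np.argmax(smoothed))
    return MechanicalSummary(
        uts=float(smoothed[peak]),
        mtm=float(best.slope),
        failure_strain=float(strain[failure_index]),
        strain_at_uts=float(strain[peak]),
        mtm_window_start_strain=float(best.start_strain),
        failure_detected=failure_detected,
        stress_convention=stress_convention,
    )


def analyze_trace(
    trace: TensileTrace,
    baseline: TensileTrace | None,
    protocol: TestProtocol,
    a0: float,
    area_convention: str = "minimum",
    stress_convention: str = "engineering",
    window_strain: float = MTM_WINDOW_STRAIN,
) -> tuple[MechanicalSummary, StressStrainCurve]:
    """Full single-specimen analysis: onset, drag subtraction, curve, endpoints.

    The tension-onset threshold is applied to the raw load before drag
    subtraction; drag subtraction then applies to the stresses.
    """
    onset, gauge = detect_tension_onset(trace, protocol)
    corrected = subtract_drag(trace, baseline) if baseline is not None else trace
    curve = to_stress_strain(corrected, onset, gauge, a0, area_convention)
    profile = tangent_modulus_profile(
        curve, window_strain=window_strain, stress_convention=stress_convention
    )
    failure_index, detected = detect_failure(
        curve.stress(stress_convention), protocol.termination_drop_fraction
    )
    summary = summarize(
        curve, profile, failure_index, detected, stress_convention=stress_convention
    )
    return summary, curve
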