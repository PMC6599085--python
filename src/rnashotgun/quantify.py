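"""XIC extraction, peak integration, and modification-state frequencies.

The quantification rule is the peak-area ratio of extracted ion chromatograms:
for one tRNA locus (one RNase T1 fragment), each wobble modification state is
an XIC target; the state's frequency is its integrated peak area divided by
the summed areas of all states of that locus.  This relies on the states
sharing fragment coordinates — ESI response of oligonucleotide anions is
driven by the phosphate backbone, not by the base modification — which is
enforced, not assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .ions import IonSpec
from .mzml_io import Run

__all__ = [
    "XICTrace",
    "PeakArea",
    "StateFrequencies",
    "extract_xic",
    "integrate_peak",
    "modification_frequencies",
    "DEFAULT_TOL_PPM",
]

DEFAULT_TOL_PPM = 20.0  # Orbitrap-class accuracy with headroom
DEFAULT_MIN_SNR = 3.0
DEFAULT_BOUNDARY_FRACTION = 0.05


class QuantifyError(ValueError):
    pass


@dataclass(frozen=True)
class XICTrace:
    """Per-scan summed intensity within an m/z window around a target."""

    mz: float
    tol_ppm: float
    rt: np.ndarray
    intensity: np.ndarray

    def __len__(self) -> int:
        return len(self.rt)


@dataclass(frozen=True)
class PeakArea:
    apex_rt: float
    rt_lo: float
    rt_hi: float
    area: float  # intensity × minutes
    detected: bool


@dataclass(frozen=True)
class StateFrequencies:
    locus_id: str
    fractions: dict[str, float]
    areas: dict[str, float]
    merged_states: tuple[str, ...] = ()  # mass-silent collisions, if any


def extract_xic(
    run: Run,
    mz: float,
    tol_ppm: float = DEFAULT_TOL_PPM,
    rt_window: Optional[tuple[float, float]] = None,
) -> XICTrace:
    """Sum centroid intensities with |obs − mz|/mz ≤ tol_ppm·1e-6, per scan."""
    if tol_ppm <= 0:
        raise QuantifyError("tol_ppm must be positive")
    half_width = mz * tol_ppm * 1e-6
    rts, values = [], []
    for scan in run.scans:
        if rt_window is not None and not (rt_window[0] <= scan.rt <= rt_window[1]):
            continue
        mask = np.abs(scan.mz - mz) <= half_width
        rts.append(scan.rt)
        values.append(float(scan.intensity[mask].sum()))
    return XICTrace(mz=mz, tol_ppm=tol_ppm, rt=np.array(rts), intensity=np.array(values))


def integrate_peak(
    trace: XICTrace,
    min_snr: float = DEFAULT_MIN_SNR,
    boundary_fraction: float = DEFAULT_BOUNDARY_FRACTION,
) -> PeakArea:
    """Trapezoidal area of the tallest chromatographic peak in a trace.

    The apex is the global maximum; bounds extend outward until intensity
    drops below ``boundary_fraction × apex`` or a valley (local minimum below
    the apex) is reached.  The peak counts as detected only when the apex
    exceeds ``min_snr`` times the baseline (median of the trace); otherwise
    the area is reported as 0.
    """
    if len(trace) == 0:
        raise QuantifyError("cannot integrate an empty trace")
    y = trace.intensity
    apex_idx = int(np.argmax(y))
    apex = float(y[apex_idx])
    baseline = float(np.median(y))
    if apex <= 0 or (baseline > 0 and apex < min_snr * baseline):
        return PeakArea(float(trace.rt[apex_idx]), trace.rt[0], trace.rt[-1], 0.0, False)
    thresh = boundary_fraction * apex

    def _walk(step: int) -> int:
        idx = apex_idx
        valley = apex
        valley_idx = apex_idx
        while 0 <= idx + step < len(y):
            nxt = y[idx + step]
            if nxt < thresh:
                break
            if nxt < valley:
                valley, valley_idx = nxt, idx + step
            elif valley < 0.5 * apex and nxt > 2.0 * valley:
                # genuine valley followed by a second peak: stop at the valley
                return valley_idx
            idx += step
        return idx

    lo = _walk(-1)
    hi = _walk(+1)
    area = float(np.trapezoid(y[lo : hi + 1], trace.rt[lo : hi + 1])) if hi > lo else 0.0
    return PeakArea(
        apex_rt=float(trace.rt[apex_idx]),
        rt_lo=float(trace.rt[lo]),
        rt_hi=float(trace.rt[hi]),
        area=area,
        detected=True,
    )


def _designated_specs(specs: Sequence[IonSpec]) -> dict[str, list[IonSpec]]:
    """Group a locus's IonSpecs by state, keeping one charge (the lowest) per state
    and all its isotopologues."""
    by_state: dict[str, list[IonSpec]] = {}
    for spec in specs:
        by_state.setdefault(spec.state, []).append(spec)
    out = {}
    for state, group in by_state.items():
        z0 = min(s.z for s in group)
        out[state] = sorted((s for s in group if s.z == z0), key=lambda s: s.k)
    return out


def modification_frequencies(
    run: Run,
    locus_specs: Sequence[IonSpec],
    tol_ppm: float = DEFAULT_TOL_PPM,
    min_snr: float = DEFAULT_MIN_SNR,
    boundary_fraction: float = DEFAULT_BOUNDARY_FRACTION,
    sum_charges: bool = False,
    rt_window: Optional[tuple[float, float]] = None,
) -> StateFrequencies:
    """Peak-area-ratio frequencies of the wobble states at one locus.

    All specs must share fragment coordinates (equal phosphate count — the
    equal-ionization assumption); violating that is an error, not a warning.
    Per state, areas of isotopologues M+0..M+k at the designated charge (the
    lowest supplied, or all charges when ``sum_charges``) are summed;
    undetected states contribute zero area.  States indistinguishable by mass
    (mass-silent isomers at identical m/z) are merged under a combined label
    with a warning.
    """
    if not locus_specs:
        raise QuantifyError("no ion specs supplied")
    coords = {(s.seq_id, s.start, s.end) for s in locus_specs}
    if len(coords) > 1:
        raise QuantifyError(
            f"ion specs span multiple loci {sorted(coords)}; "
            "peak-area ratios require identical fragment coordinates"
        )
    seq_id, start, end = next(iter(coords))
    locus_id = f"{seq_id}:{start}-{end}"
    states = {s.state for s in locus_specs}
    if len(states) < 2:
        warnings.warn(f"{locus_id}: single state supplied; frequency is trivially 1")

    if sum_charges:
        grouped: dict[str, list[IonSpec]] = {}
        for spec in locus_specs:
            grouped.setdefault(spec.state, []).append(spec)
    else:
        grouped = _designated_specs(locus_specs)

    # merge states whose target m/z coincide (mass-silent isomers)
    merged: list[str] = []
    label_of: dict[str, str] = {}
    items = sorted(grouped.items())
    for i, (state_a, specs_a) in enumerate(items):
        if state_a in label_of:
            continue
        group = [state_a]
        for state_b, specs_b in items[i + 1 :]:
            if state_b in label_of:
                continue
            if any(
                abs(sa.mz - sb.mz) < 1e-6 and sa.z == sb.z and sa.k == sb.k
                for sa in specs_a
                for sb in specs_b
            ):
                group.append(state_b)
        label = "+".join(group)
        if len(group) > 1:
            merged.append(label)
            warnings.warn(
                f"{locus_id}: states {group} are indistinguishable by mass; "
                f"reported merged as {label!r}"
            )
        for s in group:
            label_of[s] = label

    areas: dict[str, float] = {}
    for state, specs in grouped.items():
        label = label_of[state]
        total = 0.0
        for spec in specs:
            trace = extract_xic(run, spec.mz, tol_ppm, rt_window)
            if len(trace) == 0:
                continue
            total += integrate_peak(trace, min_snr, boundary_fraction).area
        areas[label] = areas.get(label, 0.0) + total

    grand_total = sum(areas.values())
    if grand_total > 0:
        fractions = {s: a / grand_total for s, a in areas.items()}
    else:
        fractions = {s: 0.0 for s in areas}
    return StateFrequencies(
        locus_id=locus_id,
        fractions=fractions,
        areas=areas,
        merged_states=tuple(merged),
    )


def frequencies_to_tsv(
    results: Sequence[StateFrequencies], run_id: str, path
) -> pd.DataFrame:
    rows = []
    for res in results:
        seq_id, locus = res.locus_id.split(":")
        for state, frac in sorted(res.fractions.items()):
            rows.append(
                {
                    "run_id": run_id,
                    "seq_id": seq_id,
                    "locus": locus,
                    "state": state,
                    "area": res.areas[state],
                    "fraction": frac,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
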