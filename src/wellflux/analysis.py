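"""Quantification pipelines: carryover percentage, ΔF/F0 normalisation and
peak extraction, Hill dose–response fitting, paired screen statistics, and
staining time-course summarisation.

Conventions (all configurable): the ΔF/F0 baseline window F0 is the final
2 s before stimulus onset; the peak window spans the stimulus plus 5 s after
it; well intensity from an image stack averages the first, middle, and last
frames over a region of interest. Screen significance uses one-sample paired
t-tests of solvent-minus-prior-control peak differences against zero, with
Bonferroni correction over the solvent×concentration comparisons at
α = 0.001. The t statistic is computed from its definition (mean·√n/sd)
rather than delegated to a library routine, so its semantics are explicit
and testable against brute force.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .plates import PlateMap, WellId
from .scheduler import Timeline
from .synthetic import CONTROL_NAME, DYE_NAME, CarryoverScan, TraceSet


class AnalysisError(ValueError):
    pass


class FitError(RuntimeError):
    """Dose–response fit failed to converge; carries diagnostics."""


# ---------------------------------------------------------------------------
# Image / frame intensities
# ---------------------------------------------------------------------------

def roi_mean_intensity(stack: np.ndarray,
                       roi: Optional[tuple[int, int, int, int]] = None,
                       frame_picks: Sequence[str] = ("first", "middle", "last")) -> float:
    """Mean intensity of selected frames, restricted to a region of interest.

    ``stack`` is ``(n_frames,)`` per-frame scalars or ``(n_frames, H, W)``
    images; ``roi`` is ``(row0, col0, height, width)`` and must lie within the
    frame. Averaging the first, middle, and last frames reduces noise without
    processing the whole stack.
    """
    a = np.asarray(stack, dtype=float)
    if a.ndim not in (1, 3):
        raise AnalysisError("stack must be 1-D (scalars) or 3-D (frames)")
    n = a.shape[0]
    if n == 0:
        raise AnalysisError("empty stack")
    idx = {"first": 0, "middle": n // 2, "last": n - 1}
    try:
        picks = [idx[p] for p in frame_picks]
    except KeyError as e:
        raise AnalysisError(f"unknown frame pick {e.args[0]!r}") from None
    frame = a[picks].mean(axis=0)
    if a.ndim == 3:
        if roi is None:
            return float(frame.mean())
        r0, c0, h, w = roi
        if r0 < 0 or c0 < 0 or r0 + h > a.shape[1] or c0 + w > a.shape[2]:
            raise AnalysisError(f"roi {roi} out of bounds for frames {a.shape[1:]}")
        return float(frame[r0:r0 + h, c0:c0 + w].mean())
    return float(frame)


def well_intensities(frames: dict[str, np.ndarray]) -> dict[str, float]:
    """First/middle/last-frame mean intensity per well."""
    return {w: roi_mean_intensity(v) for w, v in frames.items()}


# ---------------------------------------------------------------------------
# Carryover
# ---------------------------------------------------------------------------

@dataclass
class CarryoverTable:
    """Per-water-well carryover percentages and their summary."""

    table: pd.DataFrame  # columns: well, prev_dye_well, percent
    mean_percent: float
    sd_percent: float
    baseline_intensity: float

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def carryover_table(intensities: dict[str, float], plate_map: PlateMap,
                    order: Sequence[WellId],
                    baseline: Union[WellId, float],
                    dye_name: str = DYE_NAME) -> CarryoverTable:
    """Percent carryover for every buffer well that immediately follows a dye
    well along the scan order.

    All intensities are first corrected by the camera baseline — either the
    measured intensity of a designated well (e.g. A1) or a pre-run reading
    passed as a number — then each following-buffer well is expressed as a
    percentage of its immediately previous dye well:
    ``100·(I_buffer − I_base)/(I_prevDye − I_base)``.
    """
    base = intensities[str(baseline)] if isinstance(baseline, WellId) else float(baseline)
    rows = []
    for prev, cur in zip(order, order[1:]):
        if plate_map[prev].name != dye_name or plate_map[cur].name == dye_name:
            continue
        i_dye = intensities[str(prev)] - base
        i_buf = intensities[str(cur)] - base
        if i_dye <= 0:
            raise AnalysisError(
                f"well {cur}: prior dye well {prev} intensity is not above baseline; "
                "carryover ratio undefined"
            )
        rows.append((str(cur), str(prev), 100.0 * i_buf / i_dye))
    if not rows:
        raise AnalysisError("no dye-to-buffer switches found along the order")
    df = pd.DataFrame(rows, columns=["well", "prev_dye_well", "percent"])
    return CarryoverTable(df, float(df["percent"].mean()),
                          float(df["percent"].std(ddof=1)) if len(df) > 1 else 0.0,
                          base)


def analyze_carryover_scan(scan: CarryoverScan) -> CarryoverTable:
    """End-to-end carryover quantification of a synthetic (or loaded) scan,
    using the pre-run buffer acquisition as the camera baseline.

    The baseline averages the whole pre-run acquisition, not just three
    frames: its error is common to every well's percentage, so it must be
    estimated much more tightly than the per-well intensities.
    """
    intens = well_intensities(scan.frames)
    baseline = float(np.mean(scan.baseline_frames))
    return carryover_table(intens, scan.plate_map, scan.order, baseline)


# ---------------------------------------------------------------------------
# ΔF/F0 and peaks
# ---------------------------------------------------------------------------

def dff(values: np.ndarray, fps: float, stim_onset_s: float,
        f0_window_s: float = 2.0) -> np.ndarray:
    """ΔF/F0: ``(F − F0)/F0`` with F0 the mean over the ``f0_window_s``
    seconds immediately before stimulus onset."""
    f = np.asarray(values, dtype=float)
    i_on = int(round(stim_onset_s * fps))
    i0 = max(0, i_on - int(round(f0_window_s * fps)))
    if i_on <= i0:
        raise AnalysisError("empty F0 window before stimulus onset")
    f0 = f[i0:i_on].mean()
    if f0 <= 0:
        raise AnalysisError(f"non-positive F0 ({f0:g}); cannot normalise")
    return (f - f0) / f0


def peak_response(dff_values: np.ndarray, fps: float, stim_onset_s: float,
                  stim_duration_s: float, post_window_s: float = 5.0) -> float:
    """Maximum ΔF/F0 in ``[onset, onset + duration + post_window]``."""
    d = np.asarray(dff_values, dtype=float)
    i0 = int(round(stim_onset_s * fps))
    i1 = int(round((stim_onset_s + stim_duration_s + post_window_s) * fps)) + 1
    i0 = max(0, i0)
    i1 = min(len(d), i1)
    if i1 <= i0:
        raise AnalysisError("empty peak window")
    return float(d[i0:i1].max())


def extract_peaks(traces: TraceSet, f0_window_s: float = 2.0,
                  post_window_s: float = 5.0, smooth_s: float = 0.5) -> pd.DataFrame:
    """Peak ΔF/F0 per trace: the full TraceSet reduced to one row per
    (neuron/animal/well/.../pulse) group with a ``peak`` column.

    Raw fluorescence is boxcar-smoothed over ``smooth_s`` seconds before
    normalisation: taking the maximum of an unsmoothed noisy trace would add
    a noise floor to every peak (the expected maximum of N noise samples),
    biasing dose–response curves flat at low concentrations. Smoothing is
    linear, so ΔF/F0 scale invariance is preserved.
    """
    rows = []
    k = max(1, int(round(smooth_s * traces.fps)))
    if k % 2 == 0:
        k += 1
    for key, df in traces.traces():
        vals = df["value"].to_numpy(float)
        if k > 1:
            # trailing (causal) window so no post-stimulus signal leaks into
            # the pre-stimulus F0 baseline
            vals = ndimage.uniform_filter1d(vals, size=k, mode="nearest",
                                            origin=k // 2)
        onset = float(df["stim_onset_s"].iloc[0])
        dur = float(df["stim_duration_s"].iloc[0])
        d = dff(vals, traces.fps, onset, f0_window_s)
        key["peak"] = peak_response(d, traces.fps, onset, dur, post_window_s)
        rows.append(key)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dose–response fitting
# ---------------------------------------------------------------------------

def _hill_model(c: np.ndarray, bottom: float, r_max: float, log10_ec50: float,
                h: float) -> np.ndarray:
    """Four-parameter logistic: bottom + r_max·c^h/(c^h + ec50^h).

    ``bottom`` absorbs the peak-statistic noise floor (the expected maximum
    of the in-window noise); ``r_max`` is the evoked span above it.
    """
    ec50 = 10.0 ** log10_ec50
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        resp = np.where(c > 0, c ** h / (c ** h + ec50 ** h), 0.0)
    return bottom + r_max * resp


@dataclass
class DoseResponseFit:
    """Hill-fit result: parameter estimates with 95% confidence intervals,
    per-concentration summaries at both reporting conventions (per-animal
    n and per-trace n), and a display polynomial of mean peak vs log10
    concentration."""

    r_max: float
    ec50: float
    hill: float
    bottom: float
    se: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    per_conc: pd.DataFrame  # conc, mean_peak, sem_animals, n_animals, sem_traces, n_traces
    poly_coeffs: np.ndarray  # degree-3, highest power first, on log10(conc)
    warnings: list[str] = field(default_factory=list)
    n_points: int = 0

    def ec50_in_ci(self, value: float) -> bool:
        lo, hi = self.ci95["ec50"]
        return lo <= value <= hi

    def summary(self) -> str:
        lo, hi = self.ci95["ec50"]
        lines = [
            "Hill dose-response fit",
            f"  r_max = {self.r_max:.4g} (95% CI {self.ci95['r_max'][0]:.4g}"
            f"..{self.ci95['r_max'][1]:.4g})",
            f"  ec50  = {self.ec50:.4g} M (95% CI {lo:.4g}..{hi:.4g})",
            f"  hill  = {self.hill:.4g} (95% CI {self.ci95['hill'][0]:.4g}"
            f"..{self.ci95['hill'][1]:.4g})",
            f"  bottom = {self.bottom:.4g}",
            f"  n = {self.n_points} peak responses",
        ]
        lines += [f"  warning: {w}" for w in self.warnings]
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        d = {
            "r_max": self.r_max, "ec50": self.ec50, "hill": self.hill,
            "bottom": self.bottom,
            "se": self.se, "ci95": {k: list(v) for k, v in self.ci95.items()},
            "poly_coeffs": list(map(float, self.poly_coeffs)),
            "warnings": self.warnings, "n_points": self.n_points,
            "per_conc": self.per_conc.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(d, indent=1))


def dose_response_fit(peaks: pd.DataFrame, neuron: Optional[str] = None) -> DoseResponseFit:
    """Least-squares Hill fit of peak ΔF/F0 vs concentration.

    ``peaks`` needs columns ``conc`` (molar; 0 = buffer), ``animal``,
    ``pulse``, ``peak`` (and optionally ``neuron`` to select one type). The
    EC50 is fitted on a log10 scale, initialised at the first concentration
    whose mean peak exceeds half the maximum, and bounded within the tested
    span ±1 decade; an EC50 at or beyond the tested span is flagged. Raises
    :class:`FitError` on non-convergence — no silent fallback.
    """
    df = peaks
    if neuron is not None:
        df = df[df["neuron"] == neuron]
    if df.empty:
        raise AnalysisError("no peaks to fit")
    concs = np.sort(df["conc"].unique())
    pos = concs[concs > 0]
    if len(pos) < 4:
        raise AnalysisError("need at least 4 nonzero concentrations for a Hill fit")

    mean_by_conc = df.groupby("conc")["peak"].mean()
    max_mean = mean_by_conc.max()
    half = mean_by_conc[mean_by_conc.index > 0]
    above = half[half >= max_mean / 2]
    ec50_init = float(above.index.min()) if len(above) else float(np.median(pos))

    lo, hi = math.log10(pos.min()) - 1.0, math.log10(pos.max()) + 1.0
    buffer_mean = float(mean_by_conc.get(0.0, 0.0))
    p0 = [max(buffer_mean, 0.0), max(max_mean - buffer_mean, 1e-6),
          math.log10(ec50_init), 1.0]
    bounds = ([0.0, 0.0, lo, 0.1],
              [max(2.0 * abs(buffer_mean), 1.0), max(10.0 * max_mean, 1.0), hi, 10.0])

    c = df["conc"].to_numpy(float)
    y = df["peak"].to_numpy(float)
    try:
        popt, pcov = optimize.curve_fit(_hill_model, c, y, p0=p0, bounds=bounds,
                                        maxfev=20000)
    except (RuntimeError, optimize.OptimizeWarning) as e:
        raise FitError(
            f"Hill fit did not converge (n={len(y)}, concentrations={list(concs)}): {e}"
        ) from e

    bottom, r_max, log_ec50, h = popt
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    se = {"bottom": float(perr[0]), "r_max": float(perr[1]),
          "log10_ec50": float(perr[2]), "hill": float(perr[3])}
    z = 1.96
    ci95 = {
        "bottom": (float(bottom - z * perr[0]), float(bottom + z * perr[0])),
        "r_max": (float(r_max - z * perr[1]), float(r_max + z * perr[1])),
        "ec50": (float(10 ** max(log_ec50 - z * perr[2], -300.0)),
                 float(10 ** min(log_ec50 + z * perr[2], 300.0))),
        "hill": (float(h - z * perr[3]), float(h + z * perr[3])),
    }
    ec50 = float(10 ** log_ec50)

    warnings = []
    if not (pos.min() <= ec50 <= pos.max()):
        warnings.append(
            f"fitted ec50 {ec50:.3g} M lies outside the tested span "
            f"[{pos.min():.3g}, {pos.max():.3g}] M"
        )
    if not np.all(np.isfinite(perr)):
        warnings.append("parameter covariance is singular; intervals unreliable")

    # per-concentration summaries at both n conventions
    rows = []
    for conc, g in df.groupby("conc"):
        by_animal = g.groupby("animal")["peak"].mean()
        rows.append({
            "conc": float(conc),
            "mean_peak": float(g["peak"].mean()),
            "sem_animals": float(by_animal.std(ddof=1) / np.sqrt(len(by_animal)))
            if len(by_animal) > 1 else 0.0,
            "n_animals": int(len(by_animal)),
            "sem_traces": float(g["peak"].std(ddof=1) / np.sqrt(len(g)))
            if len(g) > 1 else 0.0,
            "n_traces": int(len(g)),
        })
    per_conc = pd.DataFrame(rows).sort_values("conc").reset_index(drop=True)

    # degree-3 display polynomial on log10(conc), buffer excluded
    disp = per_conc[per_conc["conc"] > 0]
    poly = np.polyfit(np.log10(disp["conc"]), disp["mean_peak"], deg=3)

    return DoseResponseFit(float(r_max), ec50, float(h), float(bottom), se, ci95,
                           per_conc, poly, warnings, n_points=len(y))


# ---------------------------------------------------------------------------
# Screen statistics
# ---------------------------------------------------------------------------

def one_sample_t(x: np.ndarray) -> tuple[float, float, int]:
    """One-sample t statistic against zero from its definition
    (mean·√n / sd) and the two-sided p-value. Returns (t, p, n);
    t is NaN for zero-variance samples (degenerate)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise AnalysisError("need at least 2 paired observations")
    sd = x.std(ddof=1)
    if sd == 0:
        return float("nan"), float("nan"), n
    t = x.mean() * math.sqrt(n) / sd
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), float(p), n


@dataclass
class ScreenResult:
    """Paired screen statistics: per solvent-concentration, the mean paired
    difference vs the immediately prior buffer control, the one-sample t
    against zero, and the Bonferroni-corrected significance flag."""

    table: pd.DataFrame  # solvent, conc, well, mean_diff, t, p, significant, degenerate, n
    alpha: float
    m: int

    def suppressors(self) -> list[tuple[str, float]]:
        sig = self.table[self.table["significant"]]
        return [(r.solvent, r.conc) for r in sig.itertuples()]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def summary(self) -> str:
        lines = [f"Screen: {self.m} comparisons, Bonferroni at alpha={self.alpha}"]
        for r in self.table.itertuples():
            flag = "*" if r.significant else " "
            lines.append(
                f" {flag} {r.solvent} {r.conc:g}%: mean diff {r.mean_diff:+.3f}, "
                f"t={r.t:.2f}, p={r.p:.2e}"
            )
        return "\n".join(lines)


def screen_stats(peaks: pd.DataFrame, plate_map: PlateMap, sequence: Sequence[WellId],
                 alpha: float = 0.001, m: Optional[int] = None,
                 control_name: str = CONTROL_NAME) -> ScreenResult:
    """Paired one-sample t-tests of solvent-minus-prior-control peak
    differences against zero (no effect), Bonferroni-corrected.

    ``peaks`` needs columns ``animal``, ``well``, ``peak``. Every solvent well
    in ``sequence`` must be immediately preceded by a control well; a missing
    prior control raises an error naming the well. ``m`` defaults to the
    number of solvent-concentration comparisons.
    """
    by_well = {w: g.set_index("animal")["peak"] for w, g in peaks.groupby("well")}
    comparisons = []
    for i, well in enumerate(sequence):
        fluid = plate_map[well]
        if fluid.name == control_name:
            continue
        if i == 0 or plate_map[sequence[i - 1]].name != control_name:
            raise AnalysisError(
                f"solvent well {well} has no immediately prior buffer control"
            )
        comparisons.append((well, sequence[i - 1], fluid))
    if not comparisons:
        raise AnalysisError("no solvent wells in the sequence")
    m = m if m is not None else len(comparisons)

    rows = []
    for well, prior, fluid in comparisons:
        s = by_well[str(well)]
        c = by_well[str(prior)]
        animals = s.index.intersection(c.index)
        if len(animals) < 2:
            raise AnalysisError(f"well {well}: need at least 2 animals with pairs")
        diffs = (s.loc[animals] - c.loc[animals]).to_numpy(float)
        t, p, n = one_sample_t(diffs)
        degenerate = math.isnan(t)
        rows.append({
            "solvent": fluid.name,
            "conc": 0.0 if fluid.concentration is None else fluid.concentration,
            "well": str(well),
            "mean_diff": float(diffs.mean()),
            "t": t, "p": p, "n": n,
            "degenerate": degenerate,
            "significant": (not degenerate) and p < alpha / m,
        })
    return ScreenResult(pd.DataFrame(rows), alpha, m)


def rm_anova_f(peaks: pd.DataFrame) -> tuple[float, int, int, float]:
    """Secondary report: one-way repeated-measures F across wells with
    animals as subjects (the primary screen statistic is the paired t path).

    Returns (F, df_condition, df_error, p).
    """
    wide = peaks.pivot_table(index="animal", columns="well", values="peak")
    wide = wide.dropna()
    y = wide.to_numpy(float)
    n, k = y.shape
    if n < 2 or k < 2:
        raise AnalysisError("repeated-measures F needs >= 2 animals and >= 2 wells")
    grand = y.mean()
    ss_cond = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    f = (ss_cond / df1) / (ss_err / df2)
    return float(f), df1, df2, float(stats.f.sf(f, df1, df2))


# ---------------------------------------------------------------------------
# Staining time-course
# ---------------------------------------------------------------------------

@dataclass
class StainingSummary:
    """Per-step mean intensities and the estimated label-onset lag."""

    step_means: pd.DataFrame  # step, fluid, t_start_min, t_end_min, mean_intensity, n_samples
    onset_lag_min: Optional[float]  # minutes after phalloidin exposure start; None if absent
    background_mean: float
    background_sd: float

    def to_csv(self, path: str | Path) -> None:
        self.step_means.to_csv(path, index=False)


def staining_curve(series: pd.DataFrame, timeline: Timeline,
                   sigma_threshold: float = 3.0) -> StainingSummary:
    """Segment a once-per-minute intensity series by the protocol's steps and
    estimate the phalloidin labelling onset.

    The onset lag is the first sampled minute at which intensity exceeds the
    pre-phalloidin background mean by ``sigma_threshold`` background SDs,
    expressed relative to the start of phalloidin exposure; ``None`` if the
    series never exceeds the threshold (flat series).
    """
    if not timeline.step_records:
        raise AnalysisError("timeline has no steps")
    minutes = series["minute"].to_numpy(float)
    values = series["value"].to_numpy(float)
    last_start_min = timeline.step_records[-1].t_fill_start / 60.0
    if minutes.max() < last_start_min:
        raise AnalysisError(
            f"series ends at {minutes.max():g} min but the final step starts at "
            f"{last_start_min:.1f} min"
        )
    rows = []
    for r in timeline.step_records:
        t0, t1 = r.t_start / 60.0, r.t_end / 60.0
        sel = (minutes >= t0) & (minutes < t1)
        rows.append({
            "step": r.index + 1, "fluid": r.fluid,
            "t_start_min": t0, "t_end_min": t1,
            "mean_intensity": float(values[sel].mean()) if sel.any() else float("nan"),
            "n_samples": int(sel.sum()),
        })
    step_means = pd.DataFrame(rows)

    phall = [r for r in timeline.step_records if "phalloidin" in r.fluid.lower()]
    onset: Optional[float] = None
    bg_mean = bg_sd = float("nan")
    if phall:
        t_exposure = phall[0].t_fill_end / 60.0
        pre = values[minutes < t_exposure]
        if len(pre) >= 2:
            bg_mean, bg_sd = float(pre.mean()), float(pre.std(ddof=1))
            threshold = bg_mean + sigma_threshold * bg_sd
            after = minutes >= t_exposure
            exceed = after & (values > threshold)
            if exceed.any():
                onset = float(minutes[exceed].min() - t_exposure)
    return StainingSummary(step_means, onset, bg_mean, bg_sd)
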