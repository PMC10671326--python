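"""Microscale-thermophoresis dilution-series analysis.

Parses capillary traces, extracts the three phase readouts (T-jump,
thermophoresis, back diffusion), fits a 1:1 mass-action isotherm with ligand
depletion for Kd per readout, and flags irregular series whose binding
constant cannot be determined (reported as "n.d.").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import least_squares

__all__ = [
    "MSTConfig",
    "MSTTrace",
    "MSTSeries",
    "Readout",
    "FitFlag",
    "KdFitResult",
    "TraceShape",
    "model_trace",
    "normalize_trace",
    "extract_readout",
    "fraction_bound",
    "fit_isotherm",
    "detect_irregularity",
    "analyze_series",
    "classify_binding",
    "binding_table",
    "read_series",
    "write_series",
]

READOUTS = ("tjump", "thermophoresis", "backdiffusion")


class Readout(str, Enum):
    tjump = "tjump"
    thermophoresis = "thermophoresis"
    backdiffusion = "backdiffusion"


class FitFlag(str, Enum):
    ok = "ok"
    no_binding = "no_binding"
    irregular = "irregular"


@dataclass(frozen=True)
class MSTConfig:
    """Instrument timing and power settings (defaults match a standard run:
    5 s before, 30 s IR-on, 5 s after, 25 s inter-capillary delay)."""

    led_power_pct: float = 40.0
    mst_power_pct: float = 40.0
    t_before_s: float = 5.0
    t_on_s: float = 30.0
    t_after_s: float = 5.0
    delay_s: float = 25.0
    sampling_hz: float = 20.0

    def __post_init__(self):
        for name in ("t_before_s", "t_on_s", "t_after_s", "delay_s", "sampling_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def t_laser_off_s(self) -> float:
        return self.t_before_s + self.t_on_s


@dataclass
class MSTTrace:
    """One capillary: time-resolved fluorescence at a fixed titrant
    concentration (molar)."""

    ligand_conc_M: float
    time_s: np.ndarray
    fluorescence: np.ndarray
    config: MSTConfig = field(default_factory=MSTConfig)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time_s.shape != self.fluorescence.shape:
            raise ValueError("time and fluorescence series differ in length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time series must be strictly increasing")
        span = self.config.t_before_s + self.config.t_on_s + self.config.t_after_s
        if self.time_s[-1] - self.time_s[0] < span - 1e-9:
            raise ValueError("trace shorter than before+on+after window")


@dataclass
class MSTSeries:
    """A dilution series of traces for one labeled RNA."""

    traces: list[MSTTrace]
    labeled_conc_M: float
    rna_id: str = ""

    def __post_init__(self):
        concs = [t.ligand_conc_M for t in self.traces]
        if any(b >= a for a, b in zip(concs, concs[1:])):
            raise ValueError("traces must be ordered by strictly decreasing concentration")
        if self.labeled_conc_M < 0:
            raise ValueError("labeled_conc_M must be >= 0")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([t.ligand_conc_M for t in self.traces])


@dataclass
class KdFitResult:
    readout: Readout
    kd_M: float  # NaN when not determined
    f_free: float
    f_bound: float
    rss: float
    amplitude: float
    flag: FitFlag
    noise_sd: float = float("nan")

    @property
    def determined(self) -> bool:
        return math.isfinite(self.kd_M)

    def kd_display(self, scale: float = 1e-6, fmt: str = "{:.2f}") -> str:
        """Kd formatted on a chosen scale (default µM), "n.d." when absent."""
        if not self.determined:
            return "n.d."
        return fmt.format(self.kd_M / scale)


# ---------------------------------------------------------------------------
# trace model (shared with the synthetic generator)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceShape:
    """Piecewise-exponential parameterization of a normalized trace.

    Cold baseline 1; on laser-on a fast T-jump exponential and a slow
    thermophoresis exponential deplete the signal; after laser-off both
    components recover, the slow one with a size-dependent back-diffusion time
    constant (bound complex diffuses back slower than free RNA). The four
    amplitudes interpolate linearly between the free and bound states.
    """

    tau_tjump_s: float = 0.3
    tau_thermo_s: float = 8.0
    a_tjump_free: float = 0.06
    a_tjump_bound: float = 0.12
    a_thermo_free: float = 0.04
    a_thermo_bound: float = 0.12
    tau_recovery_fast_s: float = 0.3
    tau_backdiff_free_s: float = 2.0
    tau_backdiff_bound_s: float = 6.0


def model_trace(
    t: np.ndarray,
    fb: float,
    config: MSTConfig | None = None,
    shape: TraceShape | None = None,
) -> np.ndarray:
    """Normalized fluorescence of the piecewise trace model at fraction bound
    ``fb``. Vectorized over ``t``."""
    config = config or MSTConfig()
    shape = shape or TraceShape()
    t = np.asarray(t, dtype=float)
    t0, t_off = config.t_before_s, config.t_laser_off_s
    a_tj = shape.a_tjump_free + (shape.a_tjump_bound - shape.a_tjump_free) * fb
    a_th = shape.a_thermo_free + (shape.a_thermo_bound - shape.a_thermo_free) * fb
    tau_bd = shape.tau_backdiff_free_s + (
        shape.tau_backdiff_bound_s - shape.tau_backdiff_free_s
    ) * fb

    out = np.ones_like(t)
    on = (t >= t0) & (t < t_off)
    dt = t[on] - t0
    out[on] = (
        1.0
        - a_tj * (1.0 - np.exp(-dt / shape.tau_tjump_s))
        - a_th * (1.0 - np.exp(-dt / shape.tau_thermo_s))
    )
    after = t >= t_off
    d_tj = a_tj * (1.0 - math.exp(-config.t_on_s / shape.tau_tjump_s))
    d_th = a_th * (1.0 - math.exp(-config.t_on_s / shape.tau_thermo_s))
    dt = t[after] - t_off
    out[after] = (
        1.0
        - d_tj * np.exp(-dt / shape.tau_recovery_fast_s)
        - d_th * np.exp(-dt / tau_bd)
    )
    return out


# ---------------------------------------------------------------------------
# readout extraction
# ---------------------------------------------------------------------------

def normalize_trace(trace: MSTTrace) -> MSTTrace:
    """Divide the trace by its cold-window mean (samples before laser-on)."""
    cold = trace.time_s < trace.time_s[0] + trace.config.t_before_s
    if cold.sum() < 5:
        raise ValueError("cold window contains fewer than 5 samples")
    mean = float(trace.fluorescence[cold].mean())
    if mean <= 0:
        raise ValueError("non-positive cold-window mean; cannot normalize")
    return replace(trace, fluorescence=trace.fluorescence / mean)


def extract_readout(trace: MSTTrace, readout: Readout | str) -> float:
    """Pull one scalar readout from a normalized trace.

    T-jump: interpolated value 1.25 s after laser-on. Thermophoresis: mean over
    the last 1 s of the IR-on window. Back diffusion: interpolated value 2.5 s
    after laser-off.
    """
    readout = Readout(readout)
    cfg = trace.config
    t = trace.time_s - trace.time_s[0]
    y = trace.fluorescence
    if readout is Readout.tjump:
        target = cfg.t_before_s + 1.25
        return _interp_checked(target, t, y)
    if readout is Readout.backdiffusion:
        target = cfg.t_laser_off_s + 2.5
        return _interp_checked(target, t, y)
    lo, hi = cfg.t_laser_off_s - 1.0, cfg.t_laser_off_s
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise ValueError("no samples in the thermophoresis window")
    return float(y[mask].mean())


def _interp_checked(target: float, t: np.ndarray, y: np.ndarray) -> float:
    if target < t[0] or target > t[-1]:
        raise ValueError(f"requested time {target:.3f}s outside recorded range")
    return float(np.interp(target, t, y))


# ---------------------------------------------------------------------------
# isotherm
# ---------------------------------------------------------------------------

def fraction_bound(L, T: float, kd: float):
    """Equilibrium fraction of the labeled species bound, 1:1 mass action with
    ligand depletion.

    Solves T·FB² − (T+L+kd)·FB + L = 0 for the physical root; evaluated in the
    numerically stable form FB = 2L / (S + sqrt(S² − 4TL)) with S = T+L+kd,
    which reduces to the hyperbola L/(L+kd) as T → 0.
    """
    if kd <= 0:
        raise ValueError("kd must be > 0")
    L = np.asarray(L, dtype=float)
    if np.any(L < 0) or T < 0:
        raise ValueError("concentrations must be >= 0")
    if T == 0:
        fb = L / (L + kd)
    else:
        s = T + L + kd
        disc = np.maximum(s * s - 4.0 * T * L, 0.0)
        fb = 2.0 * L / (s + np.sqrt(disc))
    fb = np.clip(fb, 0.0, 1.0)
    return float(fb) if fb.ndim == 0 else fb


def series_readouts(
    series: MSTSeries, readout: Readout | str
) -> tuple[np.ndarray, np.ndarray]:
    """Ligand concentrations (ascending) and the matching readout values."""
    vals = []
    for trace in series.traces:
        norm = normalize_trace(trace)
        vals.append(extract_readout(norm, readout))
    L = series.concentrations
    y = np.array(vals)
    order = np.argsort(L)
    return L[order], y[order]


def _grid_scan(
    L: np.ndarray, y: np.ndarray, T: float, kd_grid: np.ndarray
) -> tuple[float, float, float, float]:
    """For each grid Kd solve the linear least squares in (f_free, f_bound);
    return the best (kd, f_free, f_bound, rss)."""
    best = (float("nan"), 0.0, 0.0, float("inf"))
    for kd in kd_grid:
        fb = fraction_bound(L, T, kd)
        A = np.column_stack([1.0 - fb, fb])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(np.sum((A @ coef - y) ** 2))
        if rss < best[3]:
            best = (float(kd), float(coef[0]), float(coef[1]), rss)
    return best


KD_BOUNDS_M = (1e-12, 1e-2)


def fit_isotherm(
    series: MSTSeries,
    readout: Readout | str,
    noise_sd: float | None = None,
) -> KdFitResult:
    """Least-squares fit of readout(L) = f_free + (f_bound − f_free)·FB(L, T, Kd).

    Initialization: plateau estimates from the 3 lowest / 3 highest
    concentrations and a coarse log-grid scan for Kd; the refined fit runs in
    log10(Kd) within [1e-12, 1e-2] M. The ``no_binding`` flag fires when the
    fitted amplitude is below 5x the readout noise SD (estimated from fit
    residuals unless supplied).
    """
    readout = Readout(readout)
    L, y = series_readouts(series, readout)
    finite = np.isfinite(y)
    L, y = L[finite], y[finite]
    if len(L) < 4:
        raise ValueError(f"need >=4 finite readout points, got {len(L)}")
    T = series.labeled_conc_M

    lo, hi = math.log10(KD_BOUNDS_M[0]), math.log10(KD_BOUNDS_M[1])
    kd0, ff0, fb0, _ = _grid_scan(L, y, T, np.logspace(lo, hi, 81))
    ff_plateau = float(np.mean(y[:3]))
    fb_plateau = float(np.mean(y[-3:]))
    x0 = np.array([math.log10(kd0), ff0, fb0])

    def resid(x):
        kd, ff, fb_ = 10.0 ** x[0], x[1], x[2]
        return ff + (fb_ - ff) * fraction_bound(L, T, kd) - y

    try:
        sol = least_squares(
            resid,
            x0,
            bounds=([lo, -np.inf, -np.inf], [hi, np.inf, np.inf]),
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=2000,
        )
        converged = sol.success
    except Exception:
        converged = False
    if not converged:
        return KdFitResult(
            readout=readout,
            kd_M=float("nan"),
            f_free=ff_plateau,
            f_bound=fb_plateau,
            rss=float("nan"),
            amplitude=fb_plateau - ff_plateau,
            flag=FitFlag.irregular,
        )

    kd, ff, fb_ = 10.0 ** sol.x[0], float(sol.x[1]), float(sol.x[2])
    rss = float(np.sum(sol.fun**2))
    dof = max(len(L) - 3, 1)
    est_sd = math.sqrt(rss / dof)
    sd = noise_sd if noise_sd is not None else est_sd
    amplitude = fb_ - ff
    # signal span actually realized over the measured concentration range;
    # |f_bound - f_free| alone misfires when kd runs to a bound on flat data
    fb_span = fraction_bound(L[-1], T, kd) - fraction_bound(L[0], T, kd)
    flag = FitFlag.ok
    if abs(amplitude * fb_span) < 5.0 * max(sd, 1e-12):
        flag = FitFlag.no_binding
    return KdFitResult(
        readout=readout,
        kd_M=float(kd),
        f_free=ff,
        f_bound=fb_,
        rss=rss,
        amplitude=amplitude,
        flag=flag,
        noise_sd=sd,
    )


# ---------------------------------------------------------------------------
# irregularity ("n.d.") detection
# ---------------------------------------------------------------------------

def _roughness(trace: MSTTrace) -> float:
    """Median absolute second difference over the IR-on segment."""
    cfg = trace.config
    t = trace.time_s - trace.time_s[0]
    on = (t >= cfg.t_before_s) & (t < cfg.t_laser_off_s)
    seg = trace.fluorescence[on]
    if len(seg) < 3:
        return 0.0
    return float(np.median(np.abs(np.diff(seg, n=2))))


def detect_irregularity(
    series: MSTSeries,
    readout: Readout | str = Readout.thermophoresis,
    k: float = 5.0,
) -> tuple[FitFlag, dict]:
    """Flag series whose high-concentration traces are anomalously rough —
    the signature of aggregating particles.

    A series is irregular when the median trace roughness of the top-quartile
    concentrations exceeds ``k`` times that of the bottom quartile, or when
    the isotherm residuals at top concentrations exceed 3x the global residual
    SD.
    """
    readout = Readout(readout)
    traces = [normalize_trace(t) for t in series.traces]
    rough = np.array([_roughness(t) for t in traces])
    concs = series.concentrations
    order = np.argsort(concs)  # ascending
    n = len(traces)
    q = max(n // 4, 1)
    top = rough[order[-q:]]
    bottom = rough[order[:q]]
    top_med = float(np.median(top))
    bottom_med = float(np.median(bottom))
    rough_irregular = top_med > k * max(bottom_med, 1e-12)

    resid_irregular = False
    resid_info: dict = {}
    try:
        fit = fit_isotherm(series, readout)
        if fit.flag is not FitFlag.irregular:
            L, y = series_readouts(series, readout)
            pred = fit.f_free + (fit.f_bound - fit.f_free) * fraction_bound(
                L, series.labeled_conc_M, fit.kd_M
            )
            resid = y - pred
            global_sd = float(np.std(resid))
            top_resid = float(np.median(np.abs(resid[-q:])))
            resid_irregular = top_resid > 3.0 * max(global_sd, 1e-12) and global_sd > 0
            resid_info = {"residual_sd": global_sd, "top_median_abs_residual": top_resid}
    except ValueError:
        pass

    flag = FitFlag.irregular if (rough_irregular or resid_irregular) else FitFlag.ok
    diagnostics = {
        "per_trace_roughness": rough.tolist(),
        "top_median_roughness": top_med,
        "bottom_median_roughness": bottom_med,
        "roughness_ratio": top_med / max(bottom_med, 1e-12),
        "rough_irregular": rough_irregular,
        "residual_irregular": resid_irregular,
        **resid_info,
    }
    return flag, diagnostics


def analyze_series(
    series: MSTSeries,
    readouts: Sequence[Readout | str] = READOUTS,
    noise_sd: float | None = None,
    irregularity_k: float = 5.0,
) -> dict[Readout, KdFitResult]:
    """Fit every requested readout; when the series is irregular the
    thermophoresis Kd is reported as not determined."""
    flag, _ = detect_irregularity(series, k=irregularity_k)
    results: dict[Readout, KdFitResult] = {}
    for r in readouts:
        r = Readout(r)
        fit = fit_isotherm(series, r, noise_sd=noise_sd)
        if flag is FitFlag.irregular and r is Readout.thermophoresis:
            fit = replace(fit, kd_M=float("nan"), flag=FitFlag.irregular)
        results[r] = fit
    return results


def classify_binding(results: Mapping[Readout, KdFitResult]) -> str:
    """"non_binder" when every readout shows no binding signal, else "binder"."""
    if not results:
        raise ValueError("need at least one fitted readout")
    if all(r.flag is FitFlag.no_binding for r in results.values()):
        return "non_binder"
    return "binder"


def binding_table(
    per_rna: Mapping[str, Mapping[Readout, KdFitResult]], scale: float = 1e-6
) -> pd.DataFrame:
    """Summary table, one RNA per row, Kd per readout in µM with "n.d." for
    undetermined entries."""
    rows = []
    for rna, results in per_rna.items():
        row = {"rna": rna}
        for r in Readout:
            fit = results.get(r)
            if fit is None:
                row[f"kd_{r.value}_uM"] = ""
            elif fit.flag is FitFlag.no_binding:
                row[f"kd_{r.value}_uM"] = "n.d."
            else:
                row[f"kd_{r.value}_uM"] = fit.kd_display(scale)
        row["classification"] = classify_binding(results)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file interfaces
# ---------------------------------------------------------------------------

def write_series(series: MSTSeries, out_dir: str | Path) -> Path:
    """Write traces.csv (time_s, fluorescence, capillary_id) and a
    manifest.yaml describing the series; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for i, trace in enumerate(series.traces):
        frames.append(
            pd.DataFrame(
                {
                    "time_s": trace.time_s,
                    "fluorescence": trace.fluorescence,
                    "capillary_id": f"cap{i:02d}",
                }
            )
        )
    pd.concat(frames).to_csv(out / "traces.csv", index=False)
    cfg = series.traces[0].config
    manifest = {
        "rna_id": series.rna_id,
        "labeled_conc_M": float(series.labeled_conc_M),
        "traces_csv": "traces.csv",
        "capillaries": [
            {"capillary_id": f"cap{i:02d}", "ligand_conc_M": float(t.ligand_conc_M)}
            for i, t in enumerate(series.traces)
        ],
        "config": {
            "led_power_pct": cfg.led_power_pct,
            "mst_power_pct": cfg.mst_power_pct,
            "t_before_s": cfg.t_before_s,
            "t_on_s": cfg.t_on_s,
            "t_after_s": cfg.t_after_s,
            "delay_s": cfg.delay_s,
            "sampling_hz": cfg.sampling_hz,
        },
    }
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def read_series(manifest_path: str | Path) -> MSTSeries:
    manifest_path = Path(manifest_path)
    manifest = yaml.safe_load(manifest_path.read_text())
    cfg = MSTConfig(**manifest["config"])
    df = pd.read_csv(manifest_path.parent / manifest["traces_csv"])
    by_cap = dict(tuple(df.groupby("capillary_id")))
    traces = []
    for cap in manifest["capillaries"]:
        grp = by_cap[cap["capillary_id"]]
        traces.append(
            MSTTrace(
                ligand_conc_M=float(cap["ligand_conc_M"]),
                time_s=grp["time_s"].to_numpy(),
                fluorescence=grp["fluorescence"].to_numpy(),
                config=cfg,
            )
        )
    return MSTSeries(
        traces=traces,
        labeled_conc_M=float(manifest["labeled_conc_M"]),
        rna_id=manifest.get("rna_id", ""),
    )
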