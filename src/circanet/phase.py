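"""Phase and amplitude estimation and circular statistics.

Phases are hours in [0, 24) on the circadian circle. The phase of a series is
the shift phi maximizing the Pearson correlation with ``cos(2*pi*(t-phi)/24)``
— a cosinor fit by template matching; a closed-form harmonic-regression
equivalent is provided for speed. Circular summaries (mean, Fisher–Lee
correlation, wraparound distance) operate on phases converted to angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "fit_cosine_phase",
    "harmonic_regression_phase",
    "circular_mean",
    "circular_distance",
    "circular_correlation",
    "phase_shift_fraction",
    "amplitude_change_calls",
    "cross_species_shift",
    "read_homolog_phase_table",
    "MISSING_PHASE_MARKERS",
]

MISSING_PHASE_MARKERS = ("Not present", "Not oscillating")


def _hours_to_angle(phases, period: float = 24.0) -> np.ndarray:
    return np.asarray(phases, dtype=float) * 2 * np.pi / period


# -- cosinor fitting -----------------------------------------------------------


def fit_cosine_phase(
    series: np.ndarray,
    t: np.ndarray,
    period: float = 24.0,
    grid_step: float = 0.01,
    _chunk: int = 2048,
):
    """Grid-search cosinor fit: phase, amplitude, and fit correlation.

    ``series`` may be one series (1-D) or genes x timepoints. For each row the
    phase grid 0, grid_step, ..., period is scanned and the template
    ``cos(2*pi*(t-phi)/period)`` with the highest Pearson correlation wins;
    amplitude is the least-squares scale of the winning unit-amplitude
    template. Constant rows are degenerate and return NaN everywhere.
    """
    x = np.atleast_2d(np.asarray(series, dtype=float))
    t = np.asarray(t, dtype=float)
    if x.shape[1] != t.size:
        raise ValueError("series and timepoints disagree in length")
    if t.size < 4:
        raise ValueError("need at least 4 timepoints")
    omega = 2 * np.pi / period
    phis = np.arange(0.0, period, grid_step)
    templates = np.cos(omega * (t[None, :] - phis[:, None]))
    t_mean = templates.mean(axis=1, keepdims=True)
    t_cent = templates - t_mean
    t_norm = np.sqrt((t_cent**2).sum(axis=1))
    n_genes = x.shape[0]
    phase = np.full(n_genes, np.nan)
    amplitude = np.full(n_genes, np.nan)
    r_fit = np.full(n_genes, np.nan)
    for lo in range(0, n_genes, _chunk):
        hi = min(lo + _chunk, n_genes)
        xc = x[lo:hi] - x[lo:hi].mean(axis=1, keepdims=True)
        x_norm = np.sqrt((xc**2).sum(axis=1))
        ok = x_norm > 0
        corr = (xc @ t_cent.T) / np.where(x_norm[:, None] == 0, 1.0, x_norm[:, None]) / t_norm[None, :]
        best = corr.argmax(axis=1)
        idx = np.arange(hi - lo)
        phase[lo:hi] = np.where(ok, phis[best], np.nan)
        r_fit[lo:hi] = np.where(ok, corr[idx, best], np.nan)
        scale = (xc * t_cent[best]).sum(axis=1) / (t_norm[best] ** 2)
        amplitude[lo:hi] = np.where(ok, scale, np.nan)
    if np.ndim(series) == 1:
        return float(phase[0]), float(amplitude[0]), float(r_fit[0])
    return phase, amplitude, r_fit


def harmonic_regression_phase(series: np.ndarray, t: np.ndarray, period: float = 24.0):
    """Closed-form cosinor: regress on cos/sin and read the phase off atan2.

    Fits ``x = mu + b_c cos(w t) + b_s sin(w t)`` by least squares; the phase
    is ``atan2(b_s, b_c)/w mod period`` and the amplitude ``hypot(b_c, b_s)``.
    Equivalent to the grid search within one grid step on nonconstant input.
    """
    x = np.atleast_2d(np.asarray(series, dtype=float))
    t = np.asarray(t, dtype=float)
    omega = 2 * np.pi / period
    design = np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])
    coef, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    b_c, b_s = coef[1], coef[2]
    phase = (np.arctan2(b_s, b_c) / omega) % period
    phase = np.where(phase >= period, 0.0, phase)
    amplitude = np.hypot(b_c, b_s)
    constant = x.std(axis=1) == 0
    phase = np.where(constant, np.nan, phase)
    amplitude = np.where(constant, np.nan, amplitude)
    if np.ndim(series) == 1:
        return float(phase[0]), float(amplitude[0])
    return phase, amplitude


# -- circular statistics -------------------------------------------------------


def circular_mean(phases, period: float = 24.0) -> float:
    """Circular mean of phases in hours, NaN when the resultant vanishes."""
    ang = _hours_to_angle(phases, period)
    if ang.size == 0:
        raise ValueError("empty phase list")
    s, c = np.sin(ang).mean(), np.cos(ang).mean()
    if np.hypot(s, c) < 1e-9:
        return float("nan")
    out = float((np.arctan2(s, c) * period / (2 * np.pi)) % period)
    return 0.0 if out >= period else out


def circular_distance(a, b, period: float = 24.0):
    """Shortest wraparound distance between phases, in [0, period/2]."""
    d = np.abs((np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % period)
    out = np.minimum(d, period - d)
    return float(out) if np.ndim(out) == 0 else out


def circular_correlation(phases_a, phases_b, period: float = 24.0) -> float:
    """Fisher–Lee circular correlation of paired phases.

    Invariant to rotation of either variable; +1 for a pure rotation, -1 for a
    reflection. Computed with the O(n) product-sum identity of the pairwise
    definition ``sum_{i<j} sin(a_i-a_j) sin(b_i-b_j) / norm``.
    """
    a = _hours_to_angle(phases_a, period)
    b = _hours_to_angle(phases_b, period)
    if a.size != b.size:
        raise ValueError("phase vectors differ in length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    sa, ca, sb, cb = np.sin(a), np.cos(a), np.sin(b), np.cos(b)
    num = (sa @ sb) * (ca @ cb) - (sa @ cb) * (ca @ sb)
    den_a = (sa @ sa) * (ca @ ca) - (sa @ ca) ** 2
    den_b = (sb @ sb) * (cb @ cb) - (sb @ cb) ** 2
    if den_a <= 0 or den_b <= 0:
        raise ValueError("zero angular variance in one of the inputs")
    return float(num / np.sqrt(den_a * den_b))


# -- LD vs DD comparisons ------------------------------------------------------


def phase_shift_fraction(
    zcogs: pd.DataFrame, threshold: float = 4.0, period: float = 24.0
) -> tuple[int, float]:
    """Count joint calls whose LD->DD phase moved more than ``threshold`` h.

    Expects the frame produced by :func:`circanet.rhythms.call_zcogs`; only
    rows with ``zcog`` true are considered. The distance is circular, and the
    comparison is strict (exactly ``threshold`` hours is not counted).
    """
    sub = zcogs[zcogs["zcog"]] if "zcog" in zcogs else zcogs
    d = circular_distance(sub["phase_ld"].to_numpy(), sub["phase_dd"].to_numpy(), period)
    count = int(np.sum(d > threshold))
    frac = count / len(sub) if len(sub) else float("nan")
    return count, frac


def amplitude_change_calls(
    matrix_ld,
    matrix_dd,
    genes=None,
    ratio_threshold: float = 0.5,
    n_boot: int = 200,
    seed: int = 0,
    period: float = 24.0,
) -> pd.DataFrame:
    """Classify DD/LD amplitude ratios as reduced, increased, or unchanged.

    Each gene's LD and DD series get a closed-form cosinor fit; residuals are
    resampled (with replacement, independently per condition) around the fits
    and the amplitude ratio A_DD/A_LD refitted ``n_boot`` times. ``reduced``
    needs ratio < ``ratio_threshold`` with the bootstrap 95% CI excluding 1;
    ``increased`` is symmetric (ratio > 1/ratio_threshold, CI above 1);
    everything else is ``unchanged``. Zero-noise, equal-amplitude input is
    therefore ``unchanged``. Genes with zero LD amplitude come back
    ``undefined``.
    """
    ld = matrix_ld.condition("LD")
    dd = matrix_dd.condition("DD")
    if genes is None:
        genes = ld.values.index
    x_ld = ld.values.loc[genes].to_numpy(dtype=float)
    x_dd = dd.values.loc[genes].to_numpy(dtype=float)
    t_ld, t_dd = ld.timepoints(), dd.timepoints()
    rng = np.random.default_rng(seed)

    def _fit_parts(x, t):
        omega = 2 * np.pi / period
        design = np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])
        pinv = np.linalg.pinv(design)
        coef = x @ pinv.T  # genes x 3
        fitted = coef @ design.T
        amp = np.hypot(coef[:, 1], coef[:, 2])
        return design, pinv, fitted, x - fitted, amp

    d_ld, p_ld, fit_ld, res_ld, a_ld = _fit_parts(x_ld, t_ld)
    d_dd, p_dd, fit_dd, res_dd, a_dd = _fit_parts(x_dd, t_dd)

    n_genes = x_ld.shape[0]
    ratios = np.empty((n_genes, n_boot))
    for b in range(n_boot):
        i_ld = rng.integers(0, t_ld.size, size=(n_genes, t_ld.size))
        i_dd = rng.integers(0, t_dd.size, size=(n_genes, t_dd.size))
        rows = np.arange(n_genes)[:, None]
        y_ld = fit_ld + res_ld[rows, i_ld]
        y_dd = fit_dd + res_dd[rows, i_dd]
        c_ld = y_ld @ p_ld.T
        c_dd = y_dd @ p_dd.T
        amp_l = np.hypot(c_ld[:, 1], c_ld[:, 2])
        amp_d = np.hypot(c_dd[:, 1], c_dd[:, 2])
        ratios[:, b] = np.where(amp_l > 0, amp_d / np.where(amp_l == 0, 1, amp_l), np.nan)

    ratio = np.where(a_ld > 0, a_dd / np.where(a_ld == 0, 1, a_ld), np.nan)
    lo = np.nanpercentile(ratios, 2.5, axis=1)
    hi = np.nanpercentile(ratios, 97.5, axis=1)
    call = np.full(n_genes, "unchanged", dtype=object)
    call[(ratio < ratio_threshold) & (hi < 1)] = "reduced"
    call[(ratio > 1 / ratio_threshold) & (lo > 1)] = "increased"
    call[a_ld == 0] = "undefined"
    # exact equality with zero residual noise: degenerate CI, honor 'unchanged'
    zero_noise = (np.abs(res_ld).max(axis=1) < 1e-12) & (np.abs(res_dd).max(axis=1) < 1e-12)
    call[zero_noise & np.isclose(ratio, 1.0)] = "unchanged"
    return pd.DataFrame(
        {"amplitude_ratio": ratio, "ci_low": lo, "ci_high": hi, "call": call},
        index=pd.Index(genes, name="gene"),
    )


# -- cross-species phase comparison --------------------------------------------


@dataclass
class CrossSpeciesShift:
    """Result of comparing homolog phases between two species.

    ``differences`` holds per-pair (species A - species B) mod 24;
    ``mean_shift`` the circular mean of those differences, which is also the
    intercept of the unit-slope regression line phi_A = phi_B + shift (mod 24).
    """

    differences: pd.Series
    mean_shift: float
    slope: float = 1.0

    @property
    def intercept(self) -> float:
        return self.mean_shift


def read_homolog_phase_table(path) -> pd.DataFrame:
    """Read a homolog phase TSV (gene_a, gene_b, phase_a, phase_b).

    Phase columns may hold the literal markers "Not present" or
    "Not oscillating"; those rows are preserved here and excluded later by
    :func:`cross_species_shift`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 4:
        raise ValueError("homolog table needs 4 columns: gene_a, gene_b, phase_a, phase_b")
    df.columns = ["gene_a", "gene_b", "phase_a", "phase_b"] + list(df.columns[4:])
    return df


def cross_species_shift(pairs: pd.DataFrame, period: float = 24.0) -> CrossSpeciesShift:
    """Circular mean phase shift between homologous genes of two species.

    Rows whose phases are missing markers (or otherwise non-numeric) are
    dropped; the per-pair difference is (phase_a - phase_b) mod period and the
    overall shift their circular mean. The associated regression line on the
    torus has unit slope and intercept equal to the shift.
    """
    a = pd.to_numeric(pairs["phase_a"], errors="coerce")
    b = pd.to_numeric(pairs["phase_b"], errors="coerce")
    ok = a.notna() & b.notna()
    if not ok.any():
        raise ValueError("no homolog pairs with numeric phases in both species")
    diffs = ((a[ok] - b[ok]) % period).rename("phase_difference")
    if "gene_b" in pairs:
        diffs.index = pd.Index(pairs.loc[ok.to_numpy(), "gene_b"], name="gene_b")
    return CrossSpeciesShift(differences=diffs, mean_shift=circular_mean(diffs, period))
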