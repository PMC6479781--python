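"""Measurement-agreement statistics for waveforms and discrete parameters.

Waveform similarity uses Kadaba's coefficient of multiple correlation
(CMC) and RMSE; discrete parameters use normality-gated correlation
(Shapiro-Wilk deciding Pearson vs Spearman), Bland-Altman limits of
agreement, and - for between-day reliability - ICC(2,k) (two-way random
effects, absolute agreement, mean of k) with its F-based 95% confidence
interval and the standard error of measurement SEM = SD * sqrt(1 - ICC).

The ICC is computed from the two-way ANOVA mean squares directly so the
confidence-interval method stays explicit and testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
from scipy import stats as sps

from .errors import InputError
from .calibrate import GaitTensor
from .prep import DOF_NAMES

PARAM_NAMES = ("maximum", "minimum", "rom", "initial_contact")

CMC_SENTINEL = "<0.001"

CMC_BANDS = (  # lower bound (inclusive) -> label, per the published cut points
    (0.95, "excellent"),
    (0.85, "very good"),
    (0.75, "good"),
    (0.60, "moderate"),
    (0.0, "poor"),
)

ICC_BANDS = (
    (0.75, "excellent"),
    (0.40, "modest"),
    (0.0, "poor"),
)


# ---------------------------------------------------------------------------
# waveform statistics
# ---------------------------------------------------------------------------

def rmse_waveform(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square difference between two equal-length waveforms."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("rmse_waveform needs two equal-length 1-D arrays")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass
class CMCResult:
    """CMC value plus the raw radicand for diagnostics.

    A negative radicand (between-waveform variance dominating) yields the
    sentinel label ``"<0.001"`` with ``value`` NaN, matching the printed
    convention of gait-validity tables.  ``degenerate`` marks the
    all-values-identical case (defined as 1).
    """

    value: float
    radicand: float
    degenerate: bool = False

    @property
    def is_sentinel(self) -> bool:
        return not np.isfinite(self.value)

    @property
    def label(self) -> str:
        if self.is_sentinel:
            return CMC_SENTINEL
        return f"{self.value:.3f}" if self.value >= 0.001 else CMC_SENTINEL

    def floored(self) -> float:
        """Numeric value with sentinel floored to 0 (for aggregation)."""
        return 0.0 if self.is_sentinel else float(self.value)


def cmc(waveforms: np.ndarray) -> CMCResult:
    """Kadaba's coefficient of multiple correlation over M waveforms.

    ``waveforms`` is (M, T) with M >= 2.  The within-time dispersion is
    normalized by T(M-1) and the total dispersion by (MT-1); the CMC is
    the square root of one minus their ratio.
    """
    Y = np.asarray(waveforms, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 2 or Y.shape[1] < 2:
        raise InputError("cmc needs an (M >= 2, T >= 2) waveform matrix")
    if not np.all(np.isfinite(Y)):
        raise InputError("waveforms must be finite")
    M, T = Y.shape
    tmean = Y.mean(axis=0)
    gmean = Y.mean()
    num = np.sum((Y - tmean) ** 2) / (T * (M - 1))
    den = np.sum((Y - gmean) ** 2) / (M * T - 1)
    if den < 1e-300:
        return CMCResult(1.0, 1.0, degenerate=True)
    radicand = 1.0 - num / den
    if radicand < 0:
        return CMCResult(float("nan"), radicand)
    return CMCResult(float(np.sqrt(radicand)), radicand)


def classify_cmc(value) -> str:
    """Similarity band for a CMC value (sentinels are 'poor')."""
    if isinstance(value, CMCResult):
        if value.is_sentinel:
            return "poor"
        value = value.value
    if isinstance(value, str):
        return "poor"
    if not np.isfinite(value):
        return "poor"
    for lo, label in CMC_BANDS:
        if value >= lo:
            return label
    return "poor"


# ---------------------------------------------------------------------------
# discrete-parameter statistics
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    coefficient: float
    method: str                 # "pearson" | "spearman"
    p_value: float


def gated_correlation(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson correlation when both samples pass Shapiro-Wilk normality
    at ``alpha``; Spearman's rho otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 4:
        raise InputError("gated_correlation needs paired samples of n >= 4")
    if np.ptp(x) < 1e-14 or np.ptp(y) < 1e-14:
        raise InputError("correlation undefined for a constant sample")
    normal = (sps.shapiro(x).pvalue > alpha
              and sps.shapiro(y).pvalue > alpha)
    if normal:
        r = sps.pearsonr(x, y)
        return CorrelationResult(float(r.statistic), "pearson",
                                 float(r.pvalue))
    r = sps.spearmanr(x, y)
    return CorrelationResult(float(r.statistic), "spearman", float(r.pvalue))


@dataclass
class BlandAltman:
    mean_diff: float
    loa_lower: float
    loa_upper: float
    sd_diff: float


def bland_altman(x, y) -> BlandAltman:
    """Mean difference (x - y) with 95% limits of agreement."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise InputError("bland_altman needs paired samples of n >= 2")
    d = x - y
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(md, md - 1.96 * sd, md + 1.96 * sd, sd)


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def icc_2k(data: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(2,k): two-way random effects, absolute agreement, mean of k.

    ``data`` is (n_subjects, k_raters) with no missing cells.  The 95% CI
    follows McGraw & Wong's F-distribution method (as in the psych /
    pingouin implementations).  Zero between-subject variance yields ICC 0
    with the degenerate flag set.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise InputError("icc_2k needs a 2-D subjects x raters matrix")
    n, k = X.shape
    if n < 3 or k < 2:
        raise InputError("icc_2k needs n >= 3 subjects and k >= 2 raters")
    if not np.all(np.isfinite(X)):
        raise InputError("icc_2k does not accept missing cells")
    gm = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * np.sum((row_means - gm) ** 2)
    ss_cols = n * np.sum((col_means - gm) ** 2)
    ss_tot = np.sum((X - gm) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    scale = max(ss_tot, 1.0)
    if ss_rows <= 1e-12 * scale and mse <= 1e-300:
        return ICCResult(0.0, float("nan"), float("nan"), degenerate=True)

    denom = msr + (msc - mse) / n
    if abs(denom) < 1e-300:
        return ICCResult(0.0, float("nan"), float("nan"), degenerate=True)
    icc_k = (msr - mse) / denom

    if mse <= 1e-300 and msc <= 1e-300:
        # identical raters: perfect agreement, CI collapses
        return ICCResult(float(icc_k), 1.0, 1.0)

    # CI via the single-rating ICC(2,1) bounds + Spearman-Brown step-up
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        icc1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        fj = msc / mse if mse > 0 else np.inf
        term = n * (1.0 + (k - 1) * icc1) - k * icc1
        vn = (k - 1) * (n - 1) * (k * icc1 * fj + term) ** 2
        vd = (n - 1) * k ** 2 * icc1 ** 2 * fj ** 2 + term ** 2
        v = vn / vd if vd > 0 else np.nan
        f2u = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f2l = sps.f.ppf(1 - alpha / 2, v, n - 1)
        l2 = (n * (msr - f2u * mse)
              / (f2u * (k * msc + (k * n - k - n) * mse) + n * msr))
        u2 = (n * (f2l * msr - mse)
              / (k * msc + (k * n - k - n) * mse + n * f2l * msr))
    lo = l2 * k / (1.0 + l2 * (k - 1))
    hi = u2 * k / (1.0 + u2 * (k - 1))
    return ICCResult(float(icc_k), float(lo), float(hi))


def sem(sd: float, icc: float) -> float:
    """Standard error of measurement, ``SD * sqrt(1 - ICC)``.

    Negative ICCs are permitted (SEM then exceeds SD); ICC > 1 is an error.
    """
    if sd < 0:
        raise InputError("SD must be >= 0")
    if icc > 1.0 + 1e-12:
        raise InputError("ICC cannot exceed 1")
    return float(sd * np.sqrt(1.0 - min(icc, 1.0)))


def classify_icc(value: float) -> str:
    """Reliability band; values below 0 fall in the 'poor' floor."""
    if not np.isfinite(value):
        return "poor"
    for lo, label in ICC_BANDS:
        if value >= lo:
            return label
    return "poor"


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Validity or reliability summary, serializable to JSON/CSV."""

    kind: str                   # "validity" | "reliability"
    content: dict

    def to_dict(self) -> dict:
        return {"kind": self.kind, "content": self.content}

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "AgreementReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["kind"], d["content"])

    def waveform_table(self):
        """Waveform RMSE/CMC summary as a pandas DataFrame."""
        import pandas as pd

        rows = []
        for dof, per_sys in self.content["waveforms"].items():
            for system, st in per_sys.items():
                rows.append({"dof": dof, "system": system, **st})
        return pd.DataFrame(rows)

    def parameter_table(self):
        import pandas as pd

        rows = []
        for dof, per_param in self.content["parameters"].items():
            for param, per_sys in per_param.items():
                for system, st in per_sys.items():
                    flat = {}
                    for key, val in st.items():
                        if isinstance(val, dict):
                            flat.update({f"{key}_{k2}": v2
                                         for k2, v2 in val.items()})
                        else:
                            flat[key] = val
                    rows.append({"dof": dof, "parameter": param,
                                 "system": system, **flat})
        return pd.DataFrame(rows)


def _subject_mean_waveforms(g: GaitTensor) -> Dict[str, np.ndarray]:
    """Subject -> (101, 5) mean waveform, preserving first-seen order."""
    out: Dict[str, List[int]] = {}
    for i, subj in enumerate(g.subjects):
        out.setdefault(subj, []).append(i)
    return {s: g.values[idx].mean(axis=0) for s, idx in out.items()}


def _discrete_from_waveform(w: np.ndarray) -> Dict[str, np.ndarray]:
    vmax = w.max(axis=0)
    vmin = w.min(axis=0)
    return {"maximum": vmax, "minimum": vmin, "rom": vmax - vmin,
            "initial_contact": w[0]}


def _mean_sd(values: Sequence[float]) -> Dict[str, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return {"mean": float(arr.mean()), "sd": sd}


def _cmc_summary(results: List[CMCResult]) -> Dict[str, object]:
    floored = [r.floored() for r in results]
    mean = float(np.mean(floored))
    sd = float(np.std(floored, ddof=1)) if len(floored) > 1 else 0.0
    label = CMC_SENTINEL if mean < 0.001 else f"{mean:.3f}"
    return {"cmc_mean": mean, "cmc_sd": sd, "cmc_label": label,
            "n_sentinel": int(sum(r.is_sentinel for r in results)),
            "band": classify_cmc(mean)}


def validity_report(reference: GaitTensor, systems: Dict[str, GaitTensor],
                    cmc_mode: str = "system-pair") -> AgreementReport:
    """Concurrent-validity summary of one or more systems vs a reference.

    Waveform RMSE and CMC are computed per subject (on subject-mean
    cycles for ``cmc_mode="system-pair"``, on all trial waveforms of both
    systems for ``cmc_mode="trials"``) then summarized mean +/- SD across
    subjects.  Discrete parameters extracted from subject-mean waveforms
    are compared with gated correlation and Bland-Altman limits.
    """
    if cmc_mode not in ("system-pair", "trials"):
        raise InputError("cmc_mode must be 'system-pair' or 'trials'")
    ref_means = _subject_mean_waveforms(reference)
    subjects = list(ref_means)
    waveforms: dict = {dof: {} for dof in DOF_NAMES}
    parameters: dict = {dof: {p: {} for p in PARAM_NAMES}
                        for dof in DOF_NAMES}
    ref_params = {s: _discrete_from_waveform(w) for s, w in ref_means.items()}

    for name, g in systems.items():
        if set(g.subjects) != set(reference.subjects):
            raise InputError(
                f"system {name!r} does not cover the reference subjects")
        sys_means = _subject_mean_waveforms(g)
        sys_params = {s: _discrete_from_waveform(w)
                      for s, w in sys_means.items()}
        for d, dof in enumerate(DOF_NAMES):
            rmses, cmcs = [], []
            for s in subjects:
                rmses.append(rmse_waveform(sys_means[s][:, d],
                                           ref_means[s][:, d]))
                if cmc_mode == "system-pair":
                    wset = np.stack([sys_means[s][:, d], ref_means[s][:, d]])
                else:
                    idx_r = [i for i, sub in enumerate(reference.subjects)
                             if sub == s]
                    idx_s = [i for i, sub in enumerate(g.subjects)
                             if sub == s]
                    wset = np.vstack([reference.values[idx_r, :, d],
                                      g.values[idx_s, :, d]])
                cmcs.append(cmc(wset))
            entry = {"rmse_mean": float(np.mean(rmses)),
                     "rmse_sd": (float(np.std(rmses, ddof=1))
                                 if len(rmses) > 1 else 0.0)}
            entry.update(_cmc_summary(cmcs))
            waveforms[dof][name] = entry
            for param in PARAM_NAMES:
                xs = np.array([sys_params[s][param][d] for s in subjects])
                ys = np.array([ref_params[s][param][d] for s in subjects])
                st = {"system": _mean_sd(xs), "reference": _mean_sd(ys)}
                try:
                    corr = gated_correlation(xs, ys)
                    st["correlation"] = {"coefficient": corr.coefficient,
                                         "method": corr.method,
                                         "p_value": corr.p_value}
                except InputError:
                    st["correlation"] = None
                ba = bland_altman(xs, ys)
                st["bland_altman"] = {"mean_diff": ba.mean_diff,
                                      "loa_lower": ba.loa_lower,
                                      "loa_upper": ba.loa_upper}
                parameters[dof][param][name] = st

    content = {"subjects": subjects, "cmc_mode": cmc_mode,
               "waveforms": waveforms, "parameters": parameters}
    return AgreementReport("validity", content)


def reliability_report(day1: GaitTensor, day2: GaitTensor) -> AgreementReport:
    """Between-day reliability: CMC/RMSE on subject-mean waveforms plus
    ICC(2,k) and SEM per discrete parameter (subjects x days)."""
    m1 = _subject_mean_waveforms(day1)
    m2 = _subject_mean_waveforms(day2)
    subjects = [s for s in m1 if s in m2]
    if len(subjects) < 3:
        raise InputError("reliability needs at least 3 common subjects")
    p1 = {s: _discrete_from_waveform(m1[s]) for s in subjects}
    p2 = {s: _discrete_from_waveform(m2[s]) for s in subjects}
    waveforms: dict = {}
    parameters: dict = {}
    for d, dof in enumerate(DOF_NAMES):
        rmses = [rmse_waveform(m1[s][:, d], m2[s][:, d]) for s in subjects]
        cmcs = [cmc(np.stack([m1[s][:, d], m2[s][:, d]])) for s in subjects]
        entry = {"rmse_mean": float(np.mean(rmses)),
                 "rmse_sd": (float(np.std(rmses, ddof=1))
                             if len(rmses) > 1 else 0.0)}
        entry.update(_cmc_summary(cmcs))
        waveforms[dof] = {"between-day": entry}
        parameters[dof] = {}
        for param in PARAM_NAMES:
            mat = np.column_stack([
                [p1[s][param][d] for s in subjects],
                [p2[s][param][d] for s in subjects]])
            st = {"day1": _mean_sd(mat[:, 0]), "day2": _mean_sd(mat[:, 1])}
            icc = icc_2k(mat)
            sd_all = float(mat.std(ddof=1))
            st["icc"] = {"value": icc.icc, "ci_low": icc.ci_low,
                         "ci_high": icc.ci_high,
                         "band": classify_icc(icc.icc)}
            st["sem"] = sem(sd_all, icc.icc)
            parameters[dof][param] = {"between-day": st}
    content = {"subjects": subjects, "waveforms": waveforms,
               "parameters": parameters}
    return AgreementReport("reliability", content)
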