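"""Relative plasmid copy number from qPCR by the ΔΔCt method.

The copy number of a test plasmid relative to a reference plasmid is

    RQ = Ep ** ΔCt_pls / Ec ** ΔCt_chr

where Ep and Ec are the amplification efficiencies of the plasmid and
chromosomal (single-copy endogenous gene) amplicons and each ΔCt is the Ct
difference *reference − test* for that amplicon.  Efficiencies are taken
from four-parameter sigmoidal (logistic) fits of the raw amplification
curves,

    F(c) = F0 + Fmax / (1 + exp(-(c - c_half) / k)),

whose low-signal limit grows by a factor E = exp(1/k) per cycle.  Ct is
called where baseline-subtracted fluorescence crosses a fixed fraction of
the plateau, solved in closed form from the fit.  A curve simulator with
known ground truth supports end-to-end parameter-recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

PLASMID = "plasmid"
CHROMOSOME = "chromosome"
REFERENCE = "reference"
TEST = "test"

_LABELS = [(t, s) for t in (PLASMID, CHROMOSOME) for s in (REFERENCE, TEST)]


class FitFailureError(RuntimeError):
    """Sigmoid fitting failed to converge or the curve carries no signal."""


class IncompleteDesignError(ValueError):
    """Ct values missing for one of the four target × sample combinations."""


class ParameterError(ValueError):
    """A tuning parameter is outside its valid range."""


@dataclass(frozen=True)
class AmplificationCurve:
    """One raw qPCR trace: fluorescence per cycle for one well."""

    cycles: tuple[int, ...]
    fluorescence: tuple[float, ...]
    target: str          # plasmid | chromosome
    sample: str          # reference | test
    replicate: int = 1

    def __post_init__(self) -> None:
        if len(self.cycles) != len(self.fluorescence):
            raise ValueError("cycles and fluorescence differ in length")
        if any(b <= a for a, b in zip(self.cycles, self.cycles[1:])):
            raise ValueError("cycles must be strictly increasing")
        if any(f < 0 for f in self.fluorescence):
            raise ValueError("fluorescence must be non-negative")
        if self.target not in (PLASMID, CHROMOSOME) or self.sample not in (REFERENCE, TEST):
            raise ValueError("unknown curve label")


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted logistic parameters for one amplification curve."""

    F0: float
    Fmax: float
    c_half: float
    k: float
    rss: float

    def __post_init__(self) -> None:
        if self.Fmax <= 0 or self.k <= 0:
            raise ValueError("Fmax and k must be positive")


@dataclass(frozen=True)
class CopyNumberEstimate:
    """ΔΔCt result: per-amplicon efficiencies, ΔCt values and RQ."""

    Ep: float
    Ec: float
    dCt_pls: float
    dCt_chr: float
    RQ: float
    rq_spread: float | None = None

    def __post_init__(self) -> None:
        for name, e in (("Ep", self.Ep), ("Ec", self.Ec)):
            if not 1.0 < e <= 2.0 + 1e-6:
                raise ValueError(f"{name}={e:.3f} outside the per-cycle range (1, 2]")
        if self.RQ <= 0:
            raise ValueError("RQ must be positive")


def _logistic(c: np.ndarray, F0: float, Fmax: float, c_half: float, k: float) -> np.ndarray:
    return F0 + Fmax / (1.0 + np.exp(-(c - c_half) / k))


def fit_sigmoid(curve: AmplificationCurve, max_rss_frac: float = 0.25) -> SigmoidFit:
    """Least-squares four-parameter logistic fit.

    Initialiser: F0 = min signal, Fmax = signal range, c_half = cycle of the
    largest first difference, k = 1/ln 2 (perfect doubling); bounded
    optimisation.  A flat curve, non-convergence, or residuals above
    ``max_rss_frac`` of the total signal variance raise
    :class:`FitFailureError`.
    """
    c = np.asarray(curve.cycles, dtype=float)
    y = np.asarray(curve.fluorescence, dtype=float)
    if len(c) < 10:
        raise FitFailureError("need at least 10 cycles spanning baseline and plateau")
    span = float(y.max() - y.min())
    total_var = float(np.sum((y - y.mean()) ** 2))
    if span <= 0 or total_var <= 0 or span < 1e-6 * max(1.0, float(y.max())):
        raise FitFailureError("flat curve: no amplification signal")
    p0 = [float(y.min()), span, float(c[int(np.argmax(np.diff(y))) + 1]), 1.0 / math.log(2.0)]
    bounds = (
        [0.0, 1e-12, float(c.min()) - 10.0, 1e-3],
        [float(y.max()), 10.0 * span, float(c.max()) + 10.0, 100.0],
    )
    try:
        popt, _ = curve_fit(_logistic, c, y, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(f"sigmoid fit did not converge: {exc}") from exc
    rss = float(np.sum((y - _logistic(c, *popt)) ** 2))
    if rss > max_rss_frac * total_var:
        raise FitFailureError(
            f"fit rejected: rss {rss:.3g} exceeds {max_rss_frac:.0%} of signal variance"
        )
    return SigmoidFit(*map(float, popt), rss=rss)


def estimate_ct(fit: SigmoidFit, threshold_frac: float = 0.1) -> float:
    """Continuous cycle at which baseline-subtracted signal crosses the threshold.

    The threshold is ``threshold_frac × Fmax`` above baseline; from the
    logistic, ``Ct = c_half + k·ln(thr/(1−thr))`` (at thr = 0.5 this is the
    inflection cycle; thresholds below 0.5 give earlier Ct).
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ParameterError("threshold_frac must lie in (0, 1)")
    return fit.c_half + fit.k * math.log(threshold_frac / (1.0 - threshold_frac))


def efficiency_from_fit(fit: SigmoidFit) -> float:
    """Per-cycle amplification factor in the exponential limit: E = exp(1/k)."""
    if fit.k <= 0:
        raise ValueError("invalid fit: k must be positive")
    return math.exp(1.0 / fit.k)


def relative_copy_number(
    ct_table: pd.DataFrame,
    Ep: float,
    Ec: float,
) -> CopyNumberEstimate:
    """RQ from a Ct table with columns target, sample, replicate, ct.

    Replicates are averaged per label before the ΔCt differences
    (reference − test) enter ``RQ = Ep**ΔCt_pls / Ec**ΔCt_chr``.  The spread
    of replicate-wise RQ values (replicates paired by id across the four
    labels, where possible) is propagated as ``rq_spread``.
    """
    required = {"target", "sample", "ct"}
    if not required <= set(ct_table.columns):
        raise IncompleteDesignError(f"ct_table must have columns {sorted(required)}")
    means: dict[tuple[str, str], float] = {}
    for target, sample in _LABELS:
        sel = ct_table[(ct_table["target"] == target) & (ct_table["sample"] == sample)]
        if sel.empty:
            raise IncompleteDesignError(f"no Ct values for {target} × {sample}")
        means[(target, sample)] = float(sel["ct"].mean())
    dct_pls = means[(PLASMID, REFERENCE)] - means[(PLASMID, TEST)]
    dct_chr = means[(CHROMOSOME, REFERENCE)] - means[(CHROMOSOME, TEST)]
    rq = Ep ** dct_pls / Ec ** dct_chr

    spread = None
    if "replicate" in ct_table.columns:
        pivot = ct_table.pivot_table(index="replicate", columns=["target", "sample"], values="ct")
        if pivot.shape[0] > 1 and pivot.notna().all(axis=None):
            per_rep = (
                Ep ** (pivot[(PLASMID, REFERENCE)] - pivot[(PLASMID, TEST)])
                / Ec ** (pivot[(CHROMOSOME, REFERENCE)] - pivot[(CHROMOSOME, TEST)])
            )
            spread = float(per_rep.std(ddof=1))
    return CopyNumberEstimate(Ep, Ec, dct_pls, dct_chr, float(rq), spread)


def simulate_qpcr(
    template_ratio: float,
    E_p: float = 2.0,
    E_c: float = 2.0,
    noise_sd: float = 0.01,
    n_replicates: int = 3,
    rng_seed: int = 0,
    n_cycles: int = 40,
    c_half_plasmid: float = 20.0,
    c_half_chromosome: float = 22.0,
    F0: float = 0.05,
    Fmax: float = 1.0,
) -> list[AmplificationCurve]:
    """Synthetic logistic amplification curves with known ground truth.

    The test sample carries the plasmid template at ``template_ratio``-fold
    the reference, which advances its plasmid-amplicon inflection by
    ``log_E(template_ratio)`` cycles; the single-copy chromosomal amplicon is
    identical in both samples.  Multiplicative Gaussian noise of relative SD
    ``noise_sd`` is applied per reading.  Deterministic under ``rng_seed``.
    """
    if template_ratio <= 0:
        raise ParameterError("template_ratio must be positive")
    for name, e in (("E_p", E_p), ("E_c", E_c)):
        if not 1.0 < e <= 2.0:
            raise ParameterError(f"{name} must lie in (1, 2]")
    rng = np.random.default_rng(rng_seed)
    cycles = np.arange(1, n_cycles + 1, dtype=float)
    half = {
        (PLASMID, REFERENCE): c_half_plasmid,
        (PLASMID, TEST): c_half_plasmid - math.log(template_ratio, E_p),
        (CHROMOSOME, REFERENCE): c_half_chromosome,
        (CHROMOSOME, TEST): c_half_chromosome,
    }
    k = {PLASMID: 1.0 / math.log(E_p), CHROMOSOME: 1.0 / math.log(E_c)}
    curves = []
    for target, sample in _LABELS:
        for rep in range(1, n_replicates + 1):
            clean = _logistic(cycles, F0, Fmax, half[(target, sample)], k[target])
            noisy = clean * (1.0 + noise_sd * rng.standard_normal(len(cycles)))
            curves.append(
                AmplificationCurve(
                    tuple(int(c) for c in cycles),
                    tuple(np.maximum(noisy, 0.0).tolist()),
                    target, sample, rep,
                )
            )
    return curves


def copy_number_from_curves(
    curves: list[AmplificationCurve],
    threshold_frac: float = 0.1,
) -> CopyNumberEstimate:
    """Full pipeline: fit every curve, pool efficiencies, call Ct, compute RQ.

    Efficiencies are fitted per curve and pooled per amplicon by median
    across samples and replicates (robust to the occasional poor fit).
    """
    fits = {}
    rows = []
    eff: dict[str, list[float]] = {PLASMID: [], CHROMOSOME: []}
    for curve in curves:
        fit = fit_sigmoid(curve)
        fits[(curve.target, curve.sample, curve.replicate)] = fit
        eff[curve.target].append(efficiency_from_fit(fit))
        rows.append(
            {
                "target": curve.target,
                "sample": curve.sample,
                "replicate": curve.replicate,
                "ct": estimate_ct(fit, threshold_frac),
            }
        )
    if not eff[PLASMID] or not eff[CHROMOSOME]:
        raise IncompleteDesignError("curves must cover both plasmid and chromosome targets")
    ep = min(float(np.median(eff[PLASMID])), 2.0)
    ec = min(float(np.median(eff[CHROMOSOME])), 2.0)
    return relative_copy_number(pd.DataFrame(rows), ep, ec)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def curves_to_frame(curves: list[AmplificationCurve]) -> pd.DataFrame:
    rows = []
    for cv in curves:
        for c, f in zip(cv.cycles, cv.fluorescence):
            rows.append(
                {"cycle": c, "fluorescence": f, "target": cv.target,
                 "sample": cv.sample, "replicate": cv.replicate}
            )
    return pd.DataFrame(rows)


def frame_to_curves(frame: pd.DataFrame) -> list[AmplificationCurve]:
    required = {"cycle", "fluorescence", "target", "sample", "replicate"}
    if not required <= set(frame.columns):
        raise ValueError(f"curve table must have columns {sorted(required)}")
    curves = []
    for (target, sample, rep), grp in frame.groupby(["target", "sample", "replicate"]):
        grp = grp.sort_values("cycle")
        curves.append(
            AmplificationCurve(
                tuple(int(c) for c in grp["cycle"]),
                tuple(float(f) for f in grp["fluorescence"]),
                str(target), str(sample), int(rep),
            )
        )
    return curves
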