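"""Maximum-likelihood estimation of RFP tagging accuracy in a mixed
ecDNA/HSR population.

Experimental design: an ecDNA-amplified line carrying a nuclear RFP
(mCherry) label is mixed 1:1 with an unlabeled HSR-amplified line, so
the tag provides per-cell ground truth -- except that tagging is
imperfect.  Let ``Nh`` and ``Ne`` be the numbers of untagged and tagged
nuclei, ``(ch, ce)`` the untagged nuclei predicted HSR-amp and EC-amp,
``(ph, pe)`` the classifier's HSR/EC prediction probabilities given a
truly EC-amplified cell, and ``(qh, qe)`` given a truly HSR-amplified
cell (no-amp predictions did not occur).  If ``x`` of the untagged
nuclei are in truth EC-amplified cells that escaped tagging, the
probability of the observed untagged prediction counts is

    L(x) = sum_{ah=0}^{x} C(x, ah) C(Nh - x, ch - ah)
           ph^ah pe^(x-ah) qh^(ch-ah) qe^(ce+ah-x),

where ``ah`` counts untagged true-EC nuclei predicted HSR-amp.  Under a
uniform prior on 0 <= x <= Nh the MLE is the integer argmax of L; the
untagged fraction is x_hat / (Ne + x_hat) and the tagging accuracy its
complement.  A Pearson chi-square over the four (tag status x
prediction) categories checks the fit.  All likelihood evaluation is in
log space with log-gamma binomials, since Nh in the hundreds overflows
direct binomial coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

TAG_THRESHOLD = 10  # raw 0-255 intensity; tagged iff max strictly exceeds


@dataclass
class TaggingExperiment:
    """Counts and conditional prediction probabilities for the MLE."""

    Nh: int
    Ne: int
    ch: int
    ce: int
    ph: float
    pe: float
    qh: float
    qe: float
    tag_threshold: int = TAG_THRESHOLD

    def __post_init__(self) -> None:
        if min(self.Nh, self.Ne, self.ch, self.ce) < 0:
            raise ValueError("all counts must be non-negative")
        if self.ch + self.ce != self.Nh:
            raise ValueError("ch + ce must equal Nh")
        for a, b, name in ((self.ph, self.pe, "p"), (self.qh, self.qe, "q")):
            if abs(a + b - 1.0) > 1e-9:
                raise ValueError(f"{name}h + {name}e must equal 1")
            if a < 0 or b < 0:
                raise ValueError("probabilities must be non-negative")


@dataclass
class TaggingFit:
    """MLE of the untagged true-EC count with derived accuracy and fit."""

    x_hat: int
    untagged_fraction: float
    tagging_accuracy: float
    chisq: float | None = None
    df: int | None = None
    p_value: float | None = None


def tag_nucleus(
    rfp_channel: np.ndarray,
    boundary_flag: bool = False,
    threshold: int = TAG_THRESHOLD,
) -> str:
    """Tag call for one nucleus from its raw RFP intensities.

    Boundary nuclei are excluded (their maximum is unreliable: pixels
    are missing); otherwise tagged iff the maximum raw intensity
    strictly exceeds the threshold.
    """
    if boundary_flag:
        return "excluded"
    return "tagged" if int(np.asarray(rfp_channel).max()) > threshold else "untagged"


def _log_terms(x: int, exp: TaggingExperiment) -> np.ndarray:
    """Log of each valid summand of L(x) over the index ah."""
    Nh, ch, ce = exp.Nh, exp.ch, exp.ce
    ah = np.arange(0, x + 1)
    valid = (ch - ah >= 0) & (ch - ah <= Nh - x) & (ce + ah - x >= 0)
    ah = ah[valid]
    if ah.size == 0:
        return np.array([-np.inf])

    def _xlogy(k: np.ndarray, p: float) -> np.ndarray:
        # 0 * log 0 = 0; a zero probability with positive exponent kills the term
        out = np.where(k > 0, k * np.log(np.maximum(p, 1e-300)), 0.0)
        return np.where((p == 0) & (k > 0), -np.inf, out)

    log_binom_x = gammaln(x + 1) - gammaln(ah + 1) - gammaln(x - ah + 1)
    log_binom_rest = (
        gammaln(Nh - x + 1)
        - gammaln(ch - ah + 1)
        - gammaln(Nh - x - (ch - ah) + 1)
    )
    return (
        log_binom_x
        + log_binom_rest
        + _xlogy(ah, exp.ph)
        + _xlogy(x - ah, exp.pe)
        + _xlogy(ch - ah, exp.qh)
        + _xlogy(ce + ah - x, exp.qe)
    )


def tagging_log_likelihood(x: int, exp: TaggingExperiment) -> float:
    """Log of L(x); terms with invalid combinatorial arguments contribute
    zero probability."""
    if not 0 <= x <= exp.Nh:
        raise ValueError(f"x must lie in [0, {exp.Nh}]")
    return float(logsumexp(_log_terms(x, exp)))


def estimate_untagged_count(exp: TaggingExperiment) -> int:
    """Integer argmax of the tagging likelihood over 0 <= x <= Nh.

    A uniform prior over the valid range makes the posterior
    proportional to the likelihood; ties (within 1e-9 in log space, so
    that analytically flat likelihoods tie despite rounding) resolve to
    the smallest x.
    """
    log_l = np.array([tagging_log_likelihood(x, exp) for x in range(exp.Nh + 1)])
    return int(np.flatnonzero(log_l >= log_l.max() - 1e-9)[0])


def tagging_accuracy(x_hat: int, exp: TaggingExperiment) -> tuple[float, float]:
    """Untagged fraction x_hat / (Ne + x_hat) and its complement, the
    tagging accuracy, both as percentages rounded to 2 decimals."""
    if exp.Ne + x_hat == 0:
        raise ValueError("Ne + x_hat is zero; fractions undefined")
    untagged = 100.0 * x_hat / (exp.Ne + x_hat)
    return round(untagged, 2), round(100.0 - untagged, 2)


def expected_category_counts(x_hat: int, exp: TaggingExperiment) -> dict[str, float]:
    """Model-expected counts of the four (tag status x prediction) cells.

    Tagged nuclei are all true EC; untagged nuclei are x_hat true EC
    plus Nh - x_hat true HSR.
    """
    return {
        "tagged_hsr": exp.Ne * exp.ph,
        "tagged_ec": exp.Ne * exp.pe,
        "untagged_hsr": x_hat * exp.ph + (exp.Nh - x_hat) * exp.qh,
        "untagged_ec": x_hat * exp.pe + (exp.Nh - x_hat) * exp.qe,
    }


def tagging_fit_check(
    x_hat: int, exp: TaggingExperiment, observed: dict[str, int]
) -> tuple[float, int, float]:
    """Pearson chi-square of observed vs model-expected counts over the
    four (tag status x prediction) categories; df = 3.

    ``observed`` needs keys tagged_hsr, tagged_ec, untagged_hsr,
    untagged_ec and must total Nh + Ne.
    """
    expected = expected_category_counts(x_hat, exp)
    keys = ("tagged_hsr", "tagged_ec", "untagged_hsr", "untagged_ec")
    obs = np.array([observed[k] for k in keys], dtype=float)
    if int(obs.sum()) != exp.Nh + exp.Ne:
        raise ValueError("observed counts must total Nh + Ne")
    ex = np.array([expected[k] for k in keys])
    if np.any((ex == 0) & (obs > 0)):
        bad = [k for k, e, o in zip(keys, ex, obs) if e == 0 and o > 0]
        raise ValueError(f"expected count zero with observations in {bad}")
    keep = ex > 0
    stat = float(((obs[keep] - ex[keep]) ** 2 / ex[keep]).sum())
    df = 3
    return stat, df, float(stats.chi2.sf(stat, df))


def fit_tagging_experiment(
    exp: TaggingExperiment, observed: dict[str, int] | None = None
) -> TaggingFit:
    """Full pipeline: MLE, accuracy percentages, and (optionally) the
    chi-square fit check against observed four-category counts."""
    x_hat = estimate_untagged_count(exp)
    untagged, accuracy = tagging_accuracy(x_hat, exp)
    fit = TaggingFit(
        x_hat=x_hat, untagged_fraction=untagged, tagging_accuracy=accuracy
    )
    if observed is not None:
        fit.chisq, fit.df, fit.p_value = tagging_fit_check(x_hat, exp, observed)
    return fit


def simulate_tagging_experiment(
    n_nuclei: int,
    n_true_ec: int,
    n_untagged_ec: int,
    ph: float,
    pe: float,
    qh: float,
    qe: float,
    seed: int = 0,
) -> tuple[TaggingExperiment, dict[str, int]]:
    """Simulate a mixed-population tagging experiment at the count level.

    ``n_true_ec`` nuclei are truly EC-amplified, of which
    ``n_untagged_ec`` escaped tagging; the rest of the population is
    truly HSR-amplified and untagged.  Predictions are drawn per class
    from (ph, pe) and (qh, qe).  Returns the experiment (with observed
    ch, ce) and the four-category observed counts.
    """
    if n_untagged_ec > n_true_ec or n_true_ec > n_nuclei:
        raise ValueError("inconsistent simulation counts")
    rng = np.random.default_rng(seed)
    n_tagged = n_true_ec - n_untagged_ec
    n_true_hsr = n_nuclei - n_true_ec
    tagged_hsr = int(rng.binomial(n_tagged, ph))
    untagged_ec_hsr = int(rng.binomial(n_untagged_ec, ph))
    untagged_hsr_hsr = int(rng.binomial(n_true_hsr, qh))
    ch = untagged_ec_hsr + untagged_hsr_hsr
    Nh = n_untagged_ec + n_true_hsr
    exp = TaggingExperiment(
        Nh=Nh, Ne=n_tagged, ch=ch, ce=Nh - ch, ph=ph, pe=pe, qh=qh, qe=qe
    )
    observed = {
        "tagged_hsr": tagged_hsr,
        "tagged_ec": n_tagged - tagged_hsr,
        "untagged_hsr": ch,
        "untagged_ec": Nh - ch,
    }
    return exp, observed
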