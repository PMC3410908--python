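"""Two-SNP haplotype frequencies by EM and haplotype x SNP interaction.

For unphased genotypes at two biallelic loci only the double heterozygote is
phase-ambiguous: it is either (minor-minor / major-major) or (minor-major /
major-minor). EM alternates between splitting the double heterozygotes
according to current haplotype frequencies and re-estimating the
frequencies. Interaction of a haplotype with a third SNP is tested on the
posterior-expected per-subject haplotype dosage — a simplification of a full
mixture likelihood that is exact whenever phase is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import MISSING
from .pairtests import PairTestResult, test_model_constrained

__all__ = ["HAPLOTYPES", "HaplotypePosterior", "em_haplotypes",
           "test_hap_snp_interaction"]

#: haplotype labels: first letter = locus 1 allele, second = locus 2 allele;
#: uppercase is the minor allele
HAPLOTYPES = ("AB", "Ab", "aB", "ab")

# per-haplotype minor-allele indicator at (locus1, locus2)
_H_DOSE = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])


@dataclass
class HaplotypePosterior:
    """EM output: haplotype frequencies and per-subject phase posteriors.

    ``expected_dosage[k]`` is the n-vector of posterior-expected copies of
    haplotype k (0..2) per subject.
    """

    freqs: np.ndarray  # (4,) in HAPLOTYPES order
    expected_dosage: np.ndarray  # (4, n)
    log_likelihood: float
    n_iter: int
    ll_trace: list[float] | None = None  # per-iteration log-likelihood

    def dosage(self, hap: str) -> np.ndarray:
        return self.expected_dosage[HAPLOTYPES.index(hap)]


def _genotype_hap_pairs(d1: int, d2: int) -> list[tuple[int, int]]:
    """Ordered haplotype-pair configurations compatible with a genotype."""
    out = []
    for h1 in range(4):
        for h2 in range(h1, 4):
            if (_H_DOSE[h1, 0] + _H_DOSE[h2, 0] == d1
                    and _H_DOSE[h1, 1] + _H_DOSE[h2, 1] == d2):
                out.append((h1, h2))
    return out


_CONFIGS = {(i, j): _genotype_hap_pairs(i, j) for i in range(3) for j in range(3)}


def em_haplotypes(g1: np.ndarray, g2: np.ndarray, tol: float = 1e-8,
                  max_iter: int = 500) -> HaplotypePosterior:
    """Estimate two-locus haplotype frequencies by EM.

    Converges when the frequency vector moves less than ``tol`` in max norm;
    raises with an iteration trace if ``max_iter`` is exceeded.
    """
    g1 = np.asarray(g1, dtype=np.int64)
    g2 = np.asarray(g2, dtype=np.int64)
    keep = (g1 != MISSING) & (g2 != MISSING)
    g1, g2 = g1[keep], g2[keep]
    if g1.min() == g1.max() or g2.min() == g2.max():
        raise ValueError("both SNPs must be polymorphic")

    n = len(g1)
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (g1, g2), 1)

    f = np.full(4, 0.25)
    trace = []
    ll_trace: list[float] = []
    for it in range(1, max_iter + 1):
        # E-step: expected haplotype counts; only (1,1) has two configs
        hap_counts = np.zeros(4)
        w_dh = np.nan
        for (i, j), cfgs in _CONFIGS.items():
            c = counts[i, j]
            if c == 0 or not cfgs:
                continue
            if len(cfgs) == 1:
                h1, h2 = cfgs[0]
                hap_counts[h1] += c
                hap_counts[h2] += c
            else:  # double heterozygote: AB/ab vs Ab/aB
                p_cis = 2 * f[0] * f[3]
                p_trans = 2 * f[1] * f[2]
                tot = p_cis + p_trans
                w_dh = p_cis / tot if tot > 0 else 0.5
                hap_counts[[0, 3]] += c * w_dh
                hap_counts[[1, 2]] += c * (1 - w_dh)
        new_f = hap_counts / (2 * n)
        delta = float(np.abs(new_f - f).max())
        trace.append((it, delta))
        f = new_f
        ll_trace.append(_loglik(counts, f))
        if delta < tol:
            break
    else:
        raise RuntimeError(f"EM did not converge in {max_iter} iterations; "
                           f"last deltas: {trace[-5:]}")

    # posterior expected dosage per haplotype per subject
    exp_dose = np.zeros((4, n))
    p_cis = 2 * f[0] * f[3]
    p_trans = 2 * f[1] * f[2]
    w_dh = p_cis / (p_cis + p_trans) if (p_cis + p_trans) > 0 else 0.5
    for (i, j), cfgs in _CONFIGS.items():
        mask = (g1 == i) & (g2 == j)
        if not mask.any() or not cfgs:
            continue
        if len(cfgs) == 1:
            h1, h2 = cfgs[0]
            exp_dose[h1, mask] += 1
            exp_dose[h2, mask] += 1
        else:
            exp_dose[0, mask] += w_dh
            exp_dose[3, mask] += w_dh
            exp_dose[1, mask] += 1 - w_dh
            exp_dose[2, mask] += 1 - w_dh

    ll = _loglik(counts, f)
    return HaplotypePosterior(freqs=f, expected_dosage=exp_dose,
                              log_likelihood=ll, n_iter=it, ll_trace=ll_trace)


def _loglik(counts: np.ndarray, f: np.ndarray) -> float:
    ll = 0.0
    for (i, j), cfgs in _CONFIGS.items():
        c = counts[i, j]
        if c == 0:
            continue
        p = 0.0
        for h1, h2 in cfgs:
            p += (1 if h1 == h2 else 2) * f[h1] * f[h2]
        ll += c * np.log(max(p, 1e-300))
    return float(ll)


def test_hap_snp_interaction(hap: HaplotypePosterior, target_hap: str,
                             g3: np.ndarray, y: np.ndarray,
                             name: str = "hap") -> PairTestResult:
    """1-df additive interaction LRT between a haplotype's expected dosage
    and a third SNP's dosage.

    With unambiguous phase this reduces exactly to the SNP x SNP additive
    test on observed dosages. The expected-dosage substitution ignores
    phase-uncertainty in the variance, a documented simplification.
    """
    k = HAPLOTYPES.index(target_hap)
    if hap.freqs[k] <= 0:
        raise ValueError(f"target haplotype {target_hap} has frequency 0")
    dose = hap.expected_dosage[k]
    g3 = np.asarray(g3, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    keep = g3 != MISSING
    dose, g3, y = dose[keep], g3[keep], y[keep]

    res = PairTestResult(name, "g3", "addxadd", df=1)
    prod = dose * g3
    if np.ptp(prod) == 0:
        res.feasible = False
        res.df = 0
        res.reason = "constant interaction term"
        return res
    # continuous expected dosage: fit on subject-level data
    import statsmodels.api as sm
    from scipy import stats as _st
    x_red = np.column_stack([np.ones_like(dose), dose, g3.astype(float)])
    x_full = np.column_stack([x_red, prod])
    try:
        fit_full = sm.GLM(y, x_full, family=sm.families.Binomial()).fit(
            maxiter=200, tol=1e-10)
        fit_red = sm.GLM(y, x_red, family=sm.families.Binomial()).fit(
            maxiter=200, tol=1e-10)
    except Exception as exc:
        res.feasible = False
        res.reason = f"fit failed: {exc}"
        return res
    if not (fit_full.converged and fit_red.converged):
        res.feasible = False
        res.reason = "fit did not converge"
        return res
    res.statistic = max(float(fit_red.deviance - fit_full.deviance), 0.0)
    res.p = float(_st.chi2.sf(res.statistic, 1))
    res.beta_int = float(fit_full.params[-1])
    res.se_int = float(fit_full.bse[-1])
    return res
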