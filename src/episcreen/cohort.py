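"""Synthetic case-control cohort generator.

Emulates the structure of a GWAS case-control sample (a few thousand cases and
age-frequency-matched controls, biallelic SNPs under Hardy-Weinberg
equilibrium, optional pairwise linkage disequilibrium) together with logistic
two-locus disease models, so that the interaction-screening machinery can be
exercised and calibrated end to end without access-controlled genotypes.

Sampling is retrospective: a large source population is simulated from the
logistic risk model and subjects are rejection-sampled until exact case and
control quotas are met, which is how case-control studies ascertain subjects.
Under a rare disease the genotype-risk odds ratios of the source model are
preserved in the ascertained sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._coding import INTERACTION_MODELS, code_interaction

MISSING = -1  # sentinel for a missing dosage

__all__ = [
    "MISSING",
    "SnpSpec",
    "InteractionTerm",
    "DiseaseModel",
    "CohortConfig",
    "GenotypeMatrix",
    "simulate_genotypes",
    "simulate_case_control",
]


@dataclass(frozen=True)
class SnpSpec:
    """Specification of one simulated biallelic SNP.

    Parameters
    ----------
    id : str
        SNP label (e.g. ``"rs123"``).
    maf : float
        Minor-allele frequency, in (0, 0.5].
    ld_partner : str, optional
        Id of an *earlier* SNP this one is in LD with. The partner itself
        must be LD-free.
    ld_r : float
        Target haplotype (allelic) correlation with the partner, in [0, 1].
    tier : str
        Annotation category (one of the risk-factor categories, or "none").
    """

    id: str
    maf: float
    ld_partner: str | None = None
    ld_r: float = 0.0
    tier: str = "none"

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"{self.id}: maf must be in (0, 0.5], got {self.maf}")
        if self.ld_partner is None and self.ld_r != 0.0:
            raise ValueError(f"{self.id}: ld_r must be 0 without an ld_partner")
        if not 0.0 <= self.ld_r <= 1.0:
            raise ValueError(f"{self.id}: ld_r must be in [0, 1], got {self.ld_r}")


@dataclass(frozen=True)
class InteractionTerm:
    """One two-locus interaction effect in the disease model.

    ``model`` is one of ``addxadd``/``domxdom``/``recxrec`` with a scalar
    log-odds ratio ``log_or`` per unit of the coded product, or ``genotypic``
    with a 3x3 array of log-odds offsets indexed by the two dosages.
    """

    snp_a: str
    snp_b: str
    model: str = "addxadd"
    log_or: float = 0.0
    offsets: np.ndarray | None = None  # 3x3, genotypic model only

    def __post_init__(self) -> None:
        if self.model == "genotypic":
            if self.offsets is None or np.shape(self.offsets) != (3, 3):
                raise ValueError("genotypic term requires a 3x3 offsets array")
            if not np.all(np.isfinite(self.offsets)):
                raise ValueError("genotypic offsets must be finite")
        elif self.model in INTERACTION_MODELS:
            if not np.isfinite(self.log_or):
                raise ValueError("interaction log_or must be finite")
        else:
            raise ValueError(f"unknown interaction model {self.model!r}")


@dataclass(frozen=True)
class DiseaseModel:
    """Logistic disease model: logit P(D) = intercept + sum(marginal log-ORs
    x dosage) + sum(interaction terms)."""

    intercept: float
    marginal_effects: dict[str, float] = field(default_factory=dict)
    interaction_terms: tuple[InteractionTerm, ...] = ()

    def linear_predictor(self, dosages: np.ndarray, snp_ids: list[str]) -> np.ndarray:
        idx = {s: j for j, s in enumerate(snp_ids)}
        for s in self.marginal_effects:
            if s not in idx:
                raise KeyError(f"marginal effect references unknown SNP {s!r}")
        eta = np.full(dosages.shape[0], self.intercept, dtype=float)
        for s, beta in self.marginal_effects.items():
            eta += beta * dosages[:, idx[s]]
        for term in self.interaction_terms:
            if term.snp_a not in idx or term.snp_b not in idx:
                raise KeyError(f"interaction references unknown SNP pair "
                               f"({term.snp_a!r}, {term.snp_b!r})")
            da = dosages[:, idx[term.snp_a]]
            db = dosages[:, idx[term.snp_b]]
            if term.model == "genotypic":
                eta += np.asarray(term.offsets)[da, db]
            else:
                eta += term.log_or * code_interaction(da, db, term.model)
        return eta


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for one synthetic case-control cohort.

    Defaults mirror a discovery sample of 2,967 early-onset myocardial
    infarction cases and 3,075 controls.
    """

    n_cases: int = 2967
    n_controls: int = 3075
    snp_specs: tuple[SnpSpec, ...] = ()
    disease_model: DiseaseModel = field(
        default_factory=lambda: DiseaseModel(intercept=np.log(0.01 / 0.99)))
    seed: int = 0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix with optional case/control phenotype.

    ``dosages`` is n_samples x n_snps int8 in {0, 1, 2, MISSING};
    ``phenotype`` is n_samples of {0 control, 1 case} or None.
    """

    dosages: np.ndarray
    snp_ids: list[str]
    phenotype: np.ndarray | None = None
    snp_meta: dict = field(default_factory=dict)  # id -> arbitrary annotation

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.snp_ids):
            raise ValueError("dosage matrix shape does not match snp_ids")
        if self.phenotype is not None:
            self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
            if self.phenotype.shape[0] != self.dosages.shape[0]:
                raise ValueError("phenotype length does not match dosages")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_ids.index(snp_id)]

    def maf(self, snp_id: str) -> float:
        """Pooled-sample minor-allele frequency (missing excluded)."""
        d = self.column(snp_id)
        d = d[d != MISSING]
        if d.size == 0:
            return float("nan")
        f = float(d.mean()) / 2.0
        return min(f, 1.0 - f)


def _haplotype_freqs(maf_a: float, maf_b: float, r: float) -> np.ndarray:
    """Two-locus haplotype frequencies [f_AB, f_Ab, f_aB, f_ab] where capital
    letters denote the minor allele, with allelic correlation ``r``.

    Raises ValueError when ``r`` is unattainable for the given frequencies
    (Frechet bounds on the joint haplotype frequency).
    """
    pa, pb = maf_a, maf_b
    d = r * np.sqrt(pa * (1 - pa) * pb * (1 - pb))
    f_ab_joint = pa * pb + d
    lo = max(0.0, pa + pb - 1.0)
    hi = min(pa, pb)
    if not lo - 1e-12 <= f_ab_joint <= hi + 1e-12:
        raise ValueError(
            f"ld_r={r} unattainable for MAFs {pa}/{pb}: joint minor-haplotype "
            f"frequency {f_ab_joint:.4f} outside [{lo:.4f}, {hi:.4f}]")
    f = np.array([f_ab_joint, pa - f_ab_joint, pb - f_ab_joint,
                  1.0 - pa - pb + f_ab_joint])
    f = np.clip(f, 0.0, 1.0)
    return f / f.sum()


def simulate_genotypes(specs: list[SnpSpec], n: int,
                       seed: int | np.random.Generator = 0) -> GenotypeMatrix:
    """Draw ``n`` unphenotyped subjects for the given SNP specs.

    Independent SNPs are drawn as two Bernoulli(maf) alleles (HWE); each SNP
    with an ``ld_partner`` is drawn jointly with its partner from the
    two-locus haplotype distribution matching the requested correlation.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = [s.id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate SNP ids in specs")
    by_id = {s.id: s for s in specs}
    partners = [s.ld_partner for s in specs if s.ld_partner is not None]
    if len(partners) != len(set(partners)):
        raise ValueError("a SNP may serve as ld_partner of at most one other SNP")
    for s in specs:
        if s.ld_partner is not None:
            partner = by_id.get(s.ld_partner)
            if partner is None:
                raise ValueError(f"{s.id}: unknown ld_partner {s.ld_partner!r}")
            if partner.ld_partner is not None:
                raise ValueError(f"{s.id}: partner {partner.id} is itself in an LD pair")

    dosages = np.zeros((n, len(specs)), dtype=np.int8)
    col = {s: j for j, s in enumerate(ids)}
    is_partner = {s.ld_partner for s in specs if s.ld_partner is not None}
    # draws proceed in spec order; a SNP serving as an LD partner is drawn
    # jointly with its dependent SNP, everything else independently
    for s in specs:
        if s.id in is_partner:
            continue
        if s.ld_partner is None:
            dosages[:, col[s.id]] = rng.binomial(2, s.maf, size=n)
        else:
            partner = by_id[s.ld_partner]
            f = _haplotype_freqs(s.maf, partner.maf, s.ld_r)
            # two haplotypes per subject; haplotype k carries the minor
            # allele at locus "self" iff k in {0,1}, at partner iff k in {0,2}
            haps = rng.choice(4, size=(n, 2), p=f)
            dosages[:, col[s.id]] = (haps <= 1).sum(axis=1)
            dosages[:, col[partner.id]] = ((haps == 0) | (haps == 2)).sum(axis=1)
    return GenotypeMatrix(dosages, ids,
                          snp_meta={s.id: {"tier": s.tier, "maf": s.maf} for s in specs})


def _inject_missing(g: GenotypeMatrix, rate: float,
                    rng: np.random.Generator) -> GenotypeMatrix:
    mask = rng.random(g.dosages.shape) < rate
    d = g.dosages.copy()
    d[mask] = MISSING
    g.dosages = d
    return g


def simulate_case_control(config: CohortConfig,
                          max_batches: int = 2000) -> GenotypeMatrix:
    """Simulate a cohort to exact case/control quotas by rejection sampling.

    Batches of subjects are drawn from the source population, disease status
    is sampled from the logistic model, and subjects are accumulated until
    ``n_cases`` cases and ``n_controls`` controls are reached. An intercept
    implying prevalence below 1e-6 is rejected up front, since rejection
    sampling would be hopeless; raise the intercept or sample fewer cases.
    """
    specs = list(config.snp_specs)
    if not specs:
        raise ValueError("config.snp_specs is empty")
    rng = np.random.default_rng(config.seed)
    model = config.disease_model
    ids = [s.id for s in specs]

    batch = max(4 * (config.n_cases + config.n_controls), 10_000)
    probe = simulate_genotypes(specs, min(batch, 100_000), rng)
    from scipy.special import expit
    prevalence = float(expit(model.linear_predictor(
        probe.dosages.astype(np.int64), ids)).mean())
    if prevalence < 1e-6:
        raise ValueError(
            f"model prevalence ~{prevalence:.2e} < 1e-6: rejection sampling to "
            f"{config.n_cases} cases is infeasible; raise the intercept")

    kept_d: list[np.ndarray] = []
    kept_y: list[np.ndarray] = []
    have_cases = have_controls = 0
    g = probe
    for _ in range(max_batches):
        p = expit(model.linear_predictor(g.dosages.astype(np.int64), ids))
        y = (rng.random(g.n_samples) < p).astype(np.int8)
        take_case = np.flatnonzero(y == 1)[: config.n_cases - have_cases]
        take_ctrl = np.flatnonzero(y == 0)[: config.n_controls - have_controls]
        take = np.concatenate([take_case, take_ctrl])
        kept_d.append(g.dosages[take])
        kept_y.append(y[take])
        have_cases += take_case.size
        have_controls += take_ctrl.size
        if have_cases >= config.n_cases and have_controls >= config.n_controls:
            break
        g = simulate_genotypes(specs, batch, rng)
    else:
        raise RuntimeError("case/control quotas not reached; prevalence too "
                           "extreme for rejection sampling")

    dosages = np.vstack(kept_d)
    phenotype = np.concatenate(kept_y)
    order = np.argsort(-phenotype, kind="stable")  # cases first, deterministic
    out = GenotypeMatrix(dosages[order], ids, phenotype[order],
                         snp_meta={s.id: {"tier": s.tier, "maf": s.maf} for s in specs})
    if config.missing_rate > 0:
        out = _inject_missing(out, config.missing_rate, rng)
    if out.phenotype.sum() != config.n_cases:
        warnings.warn("case quota not met exactly")  # pragma: no cover
    return out
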