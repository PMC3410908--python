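"""Interaction-term codings shared by the simulator, the tests and power."""

from __future__ import annotations

import numpy as np

#: 1-df interaction models: how the product term is built from minor-allele dosages.
INTERACTION_MODELS = ("addxadd", "domxdom", "recxrec")


def code_main(d: np.ndarray, model: str) -> np.ndarray:
    """Single-locus coding matched to a 1-df interaction model.

    additive -> dosage (0,1,2); dominant -> carrier indicator; recessive ->
    double-minor-homozygote indicator.
    """
    d = np.asarray(d, dtype=float)
    if model == "addxadd":
        return d
    if model == "domxdom":
        return (d >= 1).astype(float)
    if model == "recxrec":
        return (d == 2).astype(float)
    raise ValueError(f"unknown interaction model {model!r}")


def code_interaction(d1: np.ndarray, d2: np.ndarray, model: str) -> np.ndarray:
    """Product term for a pair of dosage vectors under a 1-df model."""
    return code_main(d1, model) * code_main(d2, model)


def hwe_genotype_probs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities [P(0), P(1), P(2)] for dosage of
    the minor allele at frequency ``maf``."""
    q = float(maf)
    p = 1.0 - q
    return np.array([p * p, 2.0 * p * q, q * q])
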