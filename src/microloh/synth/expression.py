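"""Synthetic smart-seq-style count matrices for 100-cell pools.

Negative-binomial counts for two groups (reporter-negative vs
reporter-positive pools) with allele-dosage rules at three marker genes:
the receptor gene's mean is twice as high in the reporter-negative group
(two intact alleles vs one), while the recombinase and reporter transcripts
are absent there and expressed in the reporter-positive group. A chosen
number of additional genes is planted as true DEGs at a fixed |log2FC|.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..rnaseq import ExpressionMatrix

DOSAGE_GENES = ("Cx3cr1", "Cre", "Eyfp")


def _nb_counts(mean, dispersion, rng, size=None):
    """NB draws parameterized by mean and dispersion (var = m + d*m^2)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_expression(
    n_genes: int = 2_000,
    n_planted_deg: int = 32,
    effect_log2fc: float = 3.0,
    n_pairs: int = 5,
    dispersion: float = 0.01,
    base_mean: float = 300.0,
    cx3cr1_mean_pos: float = 400.0,
    reporter_mean_pos: float = 300.0,
    allele_rule: bool = True,
    seed: int = 0,
) -> ExpressionMatrix:
    """Two-group matrix with planted DEGs and allele-dosage marker genes.

    Groups are ``EYFP_neg`` and ``EYFP_pos`` with ``n_pairs`` samples each,
    paired by animal. With ``allele_rule`` the receptor gene mean in
    EYFP_neg is exactly twice that in EYFP_pos and the recombinase/reporter
    genes have mean 0 in EYFP_neg. Truth (planted DEG names, directions)
    is kept on the returned matrix.
    """
    if n_planted_deg > n_genes:
        raise ValueError("cannot plant more DEGs than genes")
    if n_pairs < 2:
        raise ValueError("need >= 2 pairs per group")
    rng = np.random.default_rng(seed)

    special = list(DOSAGE_GENES) if allele_rule else []
    # the dosage marker genes are true DEGs themselves (the receptor at
    # 2-fold, recombinase/reporter at on/off), so they count toward the
    # requested number of true DEGs
    n_bg_deg = max(0, n_planted_deg - len(special))
    n_bg = n_genes - len(special)
    genes = special + [f"gene{i:05d}" for i in range(n_bg)]
    lengths = pd.Series(
        rng.integers(500, 5_000, size=n_genes).astype(float), index=genes, name="length"
    )

    base = rng.lognormal(np.log(base_mean), 0.8, size=n_bg)
    mean_neg = dict(zip(genes[len(special):], base))
    mean_pos = dict(mean_neg)

    planted = rng.choice(genes[len(special):], size=n_bg_deg, replace=False)
    directions = rng.choice([-1.0, 1.0], size=n_bg_deg)
    for g, d in zip(planted, directions):
        mean_neg[g] = mean_neg[g] * 2.0 ** (effect_log2fc * d / 2)
        mean_pos[g] = mean_pos[g] * 2.0 ** (-effect_log2fc * d / 2)

    if allele_rule:
        mean_pos["Cx3cr1"] = cx3cr1_mean_pos
        mean_neg["Cx3cr1"] = 2.0 * cx3cr1_mean_pos
        for g in ("Cre", "Eyfp"):
            mean_pos[g] = reporter_mean_pos
            mean_neg[g] = 0.0

    samples = [f"neg_{i}" for i in range(n_pairs)] + [f"pos_{i}" for i in range(n_pairs)]
    groups = pd.Series(
        ["EYFP_neg"] * n_pairs + ["EYFP_pos"] * n_pairs, index=samples, name="group"
    )
    pairs = pd.Series(
        [f"animal_{i}" for i in range(n_pairs)] * 2, index=samples, name="pair"
    )

    data = np.zeros((n_genes, 2 * n_pairs), dtype=np.int64)
    mu_neg = np.array([mean_neg[g] for g in genes])
    mu_pos = np.array([mean_pos[g] for g in genes])
    for j in range(n_pairs):
        data[:, j] = _nb_counts(mu_neg, dispersion, rng)
        data[:, n_pairs + j] = _nb_counts(mu_pos, dispersion, rng)

    counts = pd.DataFrame(data, index=genes, columns=samples)
    return ExpressionMatrix(
        counts=counts,
        gene_lengths=lengths,
        groups=groups,
        pairs=pairs,
        truth={
            "planted_degs": sorted(planted.tolist()) + special,
            "directions": {g: float(d) for g, d in zip(planted, directions)},
            "effect_log2fc": effect_log2fc,
            "dosage_genes": special,
        },
    )
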