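import numpy as np
import pandas as pd
import pytest

from asekit.nbglmm import NbGlmmData
from asekit.simulate import SimConfig, generate_ase_counts, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact two-region cohort with planted effects, shared read-only."""
    cfg = SimConfig(
        n_aud=10,
        n_ctl=10,
        regions=("BLA", "CE"),
        n_snps=20,
        frac_differential=0.25,
        depth_mean=60.0,
        het_prob=0.6,
        seed=11,
    )
    samples, genotypes = generate_cohort(cfg)
    tables, truth = generate_ase_counts(cfg, genotypes, samples)
    return cfg, samples, genotypes, tables, truth


def make_2x2_data(counts, reps=1):
    """NbGlmmData for the saturated allele-by-group design.

    ``counts`` = (ref_ctl, alt_ctl, ref_aud, alt_aud), each replicated
    ``reps`` times.
    """
    cells = [(0, 0), (1, 0), (0, 1), (1, 1)]
    y, allele, group = [], [], []
    for c, (a, g) in zip(counts, cells):
        for _ in range(reps):
            y.append(c)
            allele.append(a)
            group.append(g)
    y = np.asarray(y, float)
    allele = np.asarray(allele, float)
    group = np.asarray(group, float)
    X = np.column_stack([np.ones_like(y), allele, group, allele * group])
    return NbGlmmData(
        y=y, X=X, names=("intercept", "allele", "group", "allele:group")
    )


def brute_force_bh(p):
    """Textbook step-up BH, quadratic-time, for cross-checking."""
    p = np.asarray(p, float)
    m = len(p)
    q = np.empty(m)
    for i in range(m):
        rank_i = np.sum(p <= p[i])  # maximal rank under ties
        candidates = [
            p[j] * m / np.sum(p <= p[j]) for j in range(m) if p[j] >= p[i]
        ]
        q[i] = min(1.0, min(candidates))
    return q
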