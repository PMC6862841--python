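import numpy as np
import pandas as pd
import pytest

from canopyselect import (
    build_a_matrix,
    simulate_breeding_values,
    simulate_pedigree,
    terminal_lines,
)
from canopyselect.synth import GeneticArchitecture, _psd_factor


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_pedigree():
    """Pedigree of ~180 F3 lines from 12 founders, with its A-matrix."""
    ped = simulate_pedigree(12, 180, 2, seed=7)
    return ped, build_a_matrix(ped)


@pytest.fixture(scope="session")
def single_trait_arch():
    return GeneticArchitecture(
        trait_names=("yield",),
        h2=[0.4],
        genetic_corr=[[1.0]],
        pheno_sd=[10.0],
        trait_means=[50.0],
    )


@pytest.fixture(scope="session")
def unreplicated_pheno(small_pedigree, single_trait_arch):
    """One plot per line: phenotype = mean + BV + residual, truth retained."""
    ped, amat = small_pedigree
    truth = simulate_breeding_values(ped, single_trait_arch, seed=9, amatrix=amat)
    lines = sorted(terminal_lines(ped))
    gen = np.random.default_rng(11)
    bv = truth.breeding_values.loc[lines, "yield"].to_numpy()
    arch = single_trait_arch
    resid_sd = np.sqrt(1 - arch.h2[0]) * arch.pheno_sd[0]
    y = arch.trait_means[0] + bv + gen.normal(0, resid_sd, len(lines))
    pheno = pd.DataFrame(
        {
            "line_id": lines,
            "yield": y,
            "field_row": np.arange(len(lines)) // 20,
            "field_col": np.arange(len(lines)) % 20,
        }
    )
    return pheno, truth, amat


def random_pedigree(n: int, seed: int) -> pd.DataFrame:
    """Random valid pedigree: each individual's parents drawn from earlier
    individuals (or unknown); includes selfing and single-known parents."""
    gen = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        ind = f"i{i:03d}"
        if i < 3 or gen.random() < 0.15:
            s = d = ""
        else:
            s = f"i{gen.integers(0, i):03d}"
            u = gen.random()
            if u < 0.2:
                d = s  # selfing
            elif u < 0.35:
                d = ""  # single known parent
            else:
                d = f"i{gen.integers(0, i):03d}"
        rows.append({"id": ind, "sire": s, "dam": d, "generation": str(i)})
    return pd.DataFrame(rows)


def kinship_oracle(ped: pd.DataFrame) -> np.ndarray:
    """Recursive coancestry f(i, j); A = 2f. Independent of the tabular path."""
    ids = list(ped["id"])
    pos = {v: k for k, v in enumerate(ids)}
    par = {
        r.id: (r.sire or None, r.dam or None)
        for r in ped.itertuples(index=False)
    }
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def f(a, b):
        if a is None or b is None:
            return 0.0
        if a == b:
            s, d = par[a]
            return 0.5 * (1.0 + f(s, d))
        # recurse on the later-born individual
        if pos[a] < pos[b]:
            a, b = b, a
        s, d = par[a]
        return 0.5 * (f(s, b) + f(d, b))

    n = len(ids)
    out = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            out[i, j] = out[j, i] = 2.0 * f(ids[i], ids[j])
    return out


__all__ = ["random_pedigree", "kinship_oracle", "_psd_factor"]
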