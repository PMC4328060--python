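"""Shared fixtures: the study family, scaled cohorts, and oracles."""

import numpy as np
import pytest

from recmap.cohort import SimConfig, simulate_cohort, study_pedigree
from recmap.pipeline import run_pipeline


@pytest.fixture(scope="session")
def family():
    return study_pedigree()


@pytest.fixture(scope="session")
def small_config():
    """Six-chromosome cohort: same per-chromosome density as the default,
    scaled for unit-test speed."""
    return SimConfig(seed=11, n_chrom=6, deletion_chrom=3)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def default_run():
    """The full pipeline on the default (29-chromosome) cohort."""
    return run_pipeline(SimConfig())


# ---------------------------------------------------------------------------
# Wright path-counting kinship oracle (independent of the recursive code)
# ---------------------------------------------------------------------------

def _ancestor_paths(ped, x):
    """All (ancestor, nodes-on-path) pairs climbing parent links from x."""
    out = []

    def climb(node, path):
        path = path + [node]
        out.append((node, frozenset(path)))
        s, d = ped.parents(node)
        for p in (s, d):
            if p is not None:
                climb(p, path)

    climb(x, [])
    return out


def oracle_kinship(ped, a, b):
    """Kinship by summing (1/2)^(n1+n2+1) (1+F_A) over all pairs of
    ancestral paths that meet only in the common ancestor A."""
    if a == b:
        s, d = ped.parents(a)
        if s is None or d is None:
            return 0.5
        return 0.5 * (1.0 + oracle_kinship(ped, s, d))
    total = 0.0
    for anc_a, path_a in _ancestor_paths(ped, a):
        for anc_b, path_b in _ancestor_paths(ped, b):
            if anc_a != anc_b or path_a & path_b != {anc_a}:
                continue
            n1, n2 = len(path_a) - 1, len(path_b) - 1
            s, d = ped.parents(anc_a)
            f_anc = 0.0 if (s is None or d is None) else oracle_kinship(ped, s, d)
            total += 0.5 ** (n1 + n2 + 1) * (1.0 + f_anc)
    return total


def random_pedigree(rng, n):
    """A random acyclic pedigree of n individuals (some founders, some with
    one or two known parents drawn from earlier individuals)."""
    from recmap.pedigree import IndividualRecord, Pedigree

    records = []
    for i in range(n):
        iid = f"I{i}"
        sire = dam = None
        if i >= 2 and rng.random() < 0.75:
            sire = f"I{rng.integers(0, i)}"
            dam = f"I{rng.integers(0, i)}"
            while dam == sire:
                dam = f"I{rng.integers(0, i)}"
            if rng.random() < 0.15:
                sire = None     # single unknown parent
        records.append(IndividualRecord(iid, sire, dam))
    return Pedigree(records)
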