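import numpy as np
import pytest

from mescreen import simulate as sim


def naive_motif_starts(seq: str) -> list[int]:
    """Brute-force oracle: slide a 6-bp window, exact match against CCCGGG."""
    motif = "CCCGGG"
    return [i for i in range(len(seq) - 5) if seq[i : i + 6] == motif]


def naive_intervals(seq: str, min_len: int, max_len: int) -> set[tuple[int, int]]:
    """Brute-force oracle: pair consecutive cut positions, filter by length."""
    cuts = [s + 3 for s in naive_motif_starts(seq)]
    out = set()
    for a, b in zip(cuts, cuts[1:]):
        if min_len <= b - a <= max_len:
            out.add((a, b))
    return out


@pytest.fixture(scope="session")
def small_msam():
    """A small screen dataset with planted loci of every class."""
    cfg = sim.MsamConfig(
        seed=11, n_invariant=400, n_tissue_specific=30, n_systemic=8,
        n_snp_artifact=4, n_cnv_artifact=4,
    )
    return sim.gen_msam(cfg), cfg


@pytest.fixture(scope="session")
def default_cohort():
    records, truth = sim.gen_cohort(sim.CohortConfig(seed=5))
    return records, truth
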