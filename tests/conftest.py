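import numpy as np
import pandas as pd
import pytest

import oncopanel as op


@pytest.fixture(scope="session")
def table3():
    """The packaged 26-row worked-example mutation table."""
    return op.table3_fixture()


@pytest.fixture(scope="session")
def small_pair():
    """One simulated 600-locus matched pair with truth (seeded)."""
    panel = op.random_panel(600, seed=11)
    params = op.SimParams(
        n_loci=600, n_somatic=4, n_germline=10, n_artifact_loci=6, seed=11
    )
    tumor, normal, truth = op.simulate_pair(panel, params)
    return panel, params, tumor, normal, truth


def make_pileup(sample_id, depths, alts, ref="A", alt_base="T", chrom="chr1"):
    """Hand-built single-alt pileup for rule-level tests."""
    n = len(depths)
    counts = {f"count_{b}": np.zeros(n, dtype=int) for b in "ACGT"}
    counts[f"count_{alt_base}"] = np.asarray(alts, dtype=int)
    frame = pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "pos": np.arange(1, n + 1),
            "ref_base": [ref] * n,
            "depth": np.asarray(depths, dtype=int),
            **counts,
        }
    )
    return op.PileupTable(sample_id=sample_id, records=frame)
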