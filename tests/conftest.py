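import numpy as np
import pandas as pd
import pytest

import af1pipe as af
from af1pipe.simulate import EffectConfig


@pytest.fixture(scope="session")
def rna_design2():
    """Full factorial RNA design, duplicates (the study's RNA layout)."""
    return af.factorial_design("RNA", 2)


@pytest.fixture(scope="session")
def rna_design3():
    return af.factorial_design("RNA", 3)


@pytest.fixture(scope="session")
def chip_design():
    """WT/FFF progestin-treated ChIP triplicates (the study's ChIP layout)."""
    return af.factorial_design("CHIP", 3, cell_lines=("WT", "FFF"), treatments=("R5020",))


@pytest.fixture(scope="session")
def mixed_fixture(rna_design2):
    """NULL-majority mixed fixture with attenuation/hyperactivity archetypes.

    2000 genes, duplicates, dispersion 0.05; DE results for the progestin
    contrast in all three PR lines, shared across tests for speed.
    """
    fractions = {
        "NULL": 0.625,
        "LIGAND_UP": 0.125,
        "ATTENUATED_FFF": 0.125,
        "HYPER_QQQ": 0.125,
    }
    truth = af.generate_truth(2000, fractions, EffectConfig(dispersion=0.05), seed=101)
    counts, _ = af.simulate_expression_counts(truth, rna_design2, seed=101)
    sf = af.compute_size_factors(counts)
    disp = af.estimate_dispersions(counts, sf, rna_design2)["dispersion"]

    def de(cell_line):
        return af.wald_test(
            counts,
            sf,
            disp,
            rna_design2,
            af.ContrastSpec(cell_line=cell_line, numerator="R5020", denominator="VEH"),
        )

    return {
        "truth": truth,
        "counts": counts,
        "design": rna_design2,
        "de_wt": de("WT"),
        "de_fff": de("FFF"),
        "de_qqq": de("QQQ"),
    }


def random_peaks(rng, n, chrom="chr1", length=1_000_000, wmin=50, wmax=400):
    starts = rng.integers(0, length - wmax - 1, size=n)
    widths = rng.integers(wmin, wmax, size=n)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + widths})


def brute_force_consensus(replicates, min_support, min_width, length=1_000_000):
    """Per-base coverage-counting oracle on a small genome."""
    from af1pipe.chip import sort_and_merge

    chroms = sorted({c for r in replicates for c in r["chrom"].unique()})
    out = []
    for chrom in chroms:
        cov = np.zeros(length, dtype=np.int32)
        for rep in replicates:
            merged = sort_and_merge(rep[rep["chrom"] == chrom])
            one = np.zeros(length, dtype=np.int32)
            for a, b in merged[["start", "end"]].to_numpy():
                one[a:b] = 1
            cov += one
        mask = (cov >= min_support).astype(np.int8)
        d = np.diff(np.concatenate([[0], mask, [0]]))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for a, b in zip(starts, ends):
            if b - a >= min_width:
                out.append({"chrom": chrom, "start": int(a), "end": int(b)})
    return pd.DataFrame(out, columns=["chrom", "start", "end"])
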