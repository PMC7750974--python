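import numpy as np
import pandas as pd
import pytest

from cphmm.io import CPG, CPH, MethylomeTable, SampleMeta, table_from_arrays


@pytest.fixture
def meta():
    return SampleMeta("s1", nonconversion_rate=0.005, mapper_ids=["0"])


def small_table(meta, rows):
    """rows: list of (chrom, pos, strand, context, motif, m, n)."""
    chrom, pos, strand, context, motif, m, n = map(list, zip(*rows))
    return table_from_arrays(chrom, np.array(pos), strand, context,
                             np.array(m), np.array(n), meta, motif=motif)


@pytest.fixture
def toy_table(meta):
    rows = [
        ("chr1", 100, "+", CPG, "CGG", 9, 10),
        ("chr1", 150, "+", CPH, "CAC", 0, 10),
        ("chr1", 200, "+", CPH, "CAC", 6, 10),
        ("chr1", 260, "-", CPG, "CGA", 7, 10),
        ("chr2", 50, "+", CPH, "CTC", 1, 12),
    ]
    return small_table(meta, rows)


def bins_frame(detected, chrom="chrT", cpg=(30, 15), cph=(200, 10), bin_size=180):
    """Uniform bin table with a given detection mask (for chain/link tests)."""
    n = len(detected)
    detected = np.asarray(detected, dtype=bool)
    df = pd.DataFrame({
        "chrom": chrom,
        "index": np.arange(n),
        "start": np.arange(n) * bin_size,
        "end": (np.arange(n) + 1) * bin_size,
        "cpg_m": cpg[1],
        "cpg_n": np.where(detected, cpg[0], 0),
        "cph_m": cph[1],
        "cph_n": np.where(detected, cph[0], 0),
    })
    df["cpg_m"] = np.minimum(df["cpg_m"], df["cpg_n"])
    df["cph_m"] = np.minimum(df["cph_m"], df["cph_n"])
    df["detected"] = detected
    return df
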