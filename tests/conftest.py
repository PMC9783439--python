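import numpy as np
import pandas as pd
import pytest

import poolts as pt


@pytest.fixture(scope="session")
def small_dataset():
    """Mostly-neutral synthetic dataset shared by read-only tests."""
    cfg, truth, counts, gene_map = pt.paper_like_dataset(seed=42, n_snps=1500)
    return {"cfg": cfg, "truth": truth, "counts": counts, "gene_map": gene_map}


@pytest.fixture(scope="session")
def small_series(small_dataset):
    ts, nv, log = pt.build_time_series(small_dataset["counts"])
    return {"ts": ts, "null_variance": nv, "filter_log": log}


def make_series(zbar, svar, years, chrom="chr01", spacing=100):
    """TimeSeriesSet from raw arrays with synthetic SNP identities."""
    zbar = np.atleast_2d(np.asarray(zbar, float))
    n = zbar.shape[0]
    snps = pd.DataFrame({"chrom": chrom, "pos": np.arange(1, n + 1) * spacing,
                         "ref": "A", "alt": "T"})
    return pt.TimeSeriesSet(snps=snps, years=np.asarray(years),
                            zbar=zbar, svar=np.broadcast_to(
                                np.asarray(svar, float), zbar.shape).copy())
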