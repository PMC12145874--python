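import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def make_scored():
    """Build a scored-genes frame (index gene_id; slfdr, deg_label) from raw values."""

    def _make(fdrs, log2fcs, alpha=0.01):
        genes = [f"g{i:03d}" for i in range(len(fdrs))]
        fdrs = np.asarray(fdrs, dtype=float)
        log2fcs = np.asarray(log2fcs, dtype=float)
        slfdr = np.log(np.maximum(fdrs, 1e-300)) * np.sign(log2fcs)
        sig = fdrs < alpha
        labels = np.where(
            sig & (log2fcs > 0), "up", np.where(sig & (log2fcs < 0), "down", "none")
        )
        return pd.DataFrame(
            {"log2fc": log2fcs, "fdr": fdrs, "slfdr": slfdr, "deg_label": labels},
            index=pd.Index(genes, name="gene_id"),
        )

    return _make
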