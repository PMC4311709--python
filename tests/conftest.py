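"""Shared fixtures: small deterministic OTU tables and design metadata."""

import numpy as np
import pandas as pd
import pytest

from rarepulse.otu import OtuTable


def make_table(counts_dict, meta_rows, taxonomy=None):
    """Build an OtuTable from {sample: [counts]} and metadata row dicts."""
    counts = pd.DataFrame.from_dict(counts_dict, orient="index")
    n_otus = counts.shape[1]
    counts.columns = [f"OTU{i + 1:03d}" for i in range(n_otus)]
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return OtuTable(counts=counts, metadata=meta, taxonomy=taxonomy or {})


def crossed_fixture(seed=42, n_eco=3, n_rep=2, n_otu=30, depth=500, treatment_shift=0.5):
    """Deterministic crossed-design table: ecosystem signal plus an optional
    rewetting shift. Used for PERMANOVA oracle comparisons."""
    rng = np.random.default_rng(seed)
    rows, meta = {}, []
    for e in range(n_eco):
        base = rng.lognormal(0, 1, n_otu)
        for trt in ["dry", "rewetted"]:
            shift = rng.lognormal(0, treatment_shift, n_otu) if trt == "rewetted" else np.ones(n_otu)
            for r in range(n_rep):
                p = base * shift * rng.lognormal(0, 0.3, n_otu)
                sid = f"E{e + 1}_{trt}_{r + 1}"
                rows[sid] = rng.multinomial(depth, p / p.sum())
                meta.append(
                    {
                        "sample": sid,
                        "ecosystem": f"E{e + 1}",
                        "treatment": trt,
                        "replicate": r + 1,
                        "pair": f"E{e + 1}R{r + 1}",
                    }
                )
    counts = pd.DataFrame.from_dict(rows, orient="index")
    counts.columns = [f"O{i}" for i in range(n_otu)]
    return OtuTable(counts=counts, metadata=pd.DataFrame(meta).set_index("sample"))


@pytest.fixture
def tiny_pair_table():
    """2 samples x 3 OTUs forming one dry/rewetted pair."""
    return make_table(
        {"u1_dry": [5, 1, 0], "u1_rewetted": [2, 0, 7]},
        [
            {"sample": "u1_dry", "ecosystem": "E1", "treatment": "dry", "replicate": 1, "pair": "E1R1"},
            {"sample": "u1_rewetted", "ecosystem": "E1", "treatment": "rewetted", "replicate": 1, "pair": "E1R1"},
        ],
    )
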