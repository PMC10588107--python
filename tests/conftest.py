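import numpy as np
import pandas as pd
import pytest

from clustercall import MarkerDatabase, SyntheticConfig, make_database, make_marker_table, make_truth


def make_db(records, synonyms=None):
    """Build a MarkerDatabase from (tissue, cell_type, gene[, species]) tuples."""
    rows = [r if len(r) == 4 else (*r, "both") for r in records]
    rec = pd.DataFrame(rows, columns=["tissue", "cell_type", "gene", "species"])
    rec["gene_key"] = rec["gene"].str.strip().str.upper()
    return MarkerDatabase(rec, dict(synonyms or {}))


@pytest.fixture
def pancreas_db():
    return make_db(
        [
            ("pancreas", "beta cell", "INS"),
            ("pancreas", "beta cell", "IAPP"),
            ("pancreas", "alpha cell", "GCG"),
            ("pancreas", "alpha cell", "TTR"),
            ("pancreas", "delta cell", "SST"),
            ("pancreas", "delta cell", "TTR"),  # shared marker
        ]
    )


@pytest.fixture
def marker_table():
    """Small canonical-layout table: cluster c0 is beta-like, c1 alpha-like."""
    return pd.DataFrame(
        {
            "cluster": ["c0", "c0", "c0", "c1", "c1", "c1"],
            "gene": ["INS", "IAPP", "JUNK1", "GCG", "TTR", "JUNK2"],
            "avg_log2fc": [3.0, 2.0, 0.2, 2.5, 1.5, 0.1],
            "pct_in": [0.9, 0.7, 0.5, 0.8, 0.6, 0.4],
            "pct_out": [0.05, 0.02, 0.4, 0.04, 0.1, 0.5],
            "p_adj": [1e-20, 1e-10, 0.2, 1e-15, 1e-8, 0.5],
        }
    )


@pytest.fixture
def scenario():
    """Default synthetic scenario: db, planted truth, marker table."""
    cfg = SyntheticConfig(seed=11)
    db = make_database(cfg)
    truth = make_truth(db, cfg)
    table = make_marker_table(db, truth, cfg)
    return cfg, db, truth, table
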