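"""Shared fixtures: synthetic studies and hand-built comparison results."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lfqcarto import StudyConfig, generate_study
from lfqcarto.diffexpr import ComparisonResult


def make_comparison_result(
    name: str, rows: dict, n_pairs: int = 5
) -> ComparisonResult:
    """Build a ComparisonResult from {gene: (t, p)} (or (t, p, degenerate))."""
    genes = sorted(rows)
    recs = []
    for g in genes:
        row = rows[g]
        t, p = row[0], row[1]
        degenerate = bool(row[2]) if len(row) > 2 else False
        recs.append(
            {
                "t_stat": float(t),
                "p_value": float(p),
                "fold_change": 1.0,
                "n_pairs": n_pairs,
                "degenerate": degenerate,
            }
        )
    table = pd.DataFrame(recs, index=pd.Index(genes, name="gene"))
    return ComparisonResult(contrast=name, table=table)


@pytest.fixture(scope="session")
def marker_study():
    """Default-condition study with planted tumor and zone markers."""
    cfg = StudyConfig(seed=1)
    return cfg, *generate_study(cfg)


@pytest.fixture(scope="session")
def small_study():
    """A small, fast study for plumbing tests (still fully structured)."""
    cfg = StudyConfig(n_proteins=300, seed=42)
    return cfg, *generate_study(cfg)


@pytest.fixture(scope="session")
def null_study():
    """No planted effects, no dropout: the calibration dataset."""
    cfg = StudyConfig(n_proteins=2500, seed=11).null()
    return cfg, *generate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
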