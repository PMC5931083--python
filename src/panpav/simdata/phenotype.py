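"""Quantitative-trait simulation on top of a PAV truth matrix.

The trait is a sum of three parts: a causal presence/absence marker, a
polygenic term built from all other dispensable markers (which inherits
the cohort's group structure and so induces confounding, the situation a
kinship mixed model exists to handle), and independent noise.  Components
are empirically standardized and mixed so the genetic share of the trait
variance equals the configured heritability exactly in-sample.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import SimConfig

logger = logging.getLogger(__name__)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def resolve_causal_gene(truth, config: SimConfig) -> str | None:
    """Pick the causal gene: an explicit id, or the dispensable gene whose
    cohort frequency is closest to 0.5 (``"auto"``)."""
    if config.causal_gene is None:
        return None
    disp = [g.gene_id for g in truth.genes if g.gene_id.startswith("disp_")]
    if config.causal_gene != "auto":
        if config.causal_gene not in truth.presence.row_ids:
            raise KeyError(f"causal gene {config.causal_gene!r} not in the truth matrix")
        return config.causal_gene
    if not disp:
        return None
    freqs = truth.presence.df.loc[disp].mean(axis=1)
    return (freqs - 0.5).abs().sort_values(kind="stable").index[0]


def simulate_phenotype(
    truth, config: SimConfig | None = None, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate one trait value per accession; deterministic given the seed.

    Genetic variance (causal + polygenic) makes up ``heritability`` of the
    trait variance, with the causal marker carrying ``causal_share`` of
    the genetic part.  A monomorphic causal gene contributes nothing
    (warned); noise is orthogonalized against the genetic score so the
    in-sample variance split is exact.
    """
    config = config or truth.config
    if rng is None:
        rng = np.random.default_rng([config.seed, 5])
    accs = truth.accessions
    n = len(accs)
    X = truth.presence.values().astype(float)  # genes x accessions
    disp_rows = [i for i, g in enumerate(truth.presence.row_ids) if g.startswith("disp_")]
    causal = resolve_causal_gene(truth, config)
    h2 = config.heritability
    share = config.causal_share if causal is not None else 0.0

    c = np.zeros(n)
    if causal is not None:
        c = X[truth.presence.row_ids.index(causal)]
        if np.ptp(c) == 0:
            logger.warning("causal gene %s is monomorphic; no causal effect", causal)
            share = 0.0
    poly_rows = [i for i in disp_rows if truth.presence.row_ids[i] != causal]
    if poly_rows:
        W = X[poly_rows]
        w = rng.normal(size=len(poly_rows))
        u = w @ (W - W.mean(axis=1, keepdims=True))
    else:
        u = np.zeros(n)

    g = np.sqrt(share) * _standardize(c) + np.sqrt(1 - share) * _standardize(u)
    g = _standardize(g)
    e = rng.normal(size=n)
    if g.std() > 0:  # orthogonalize noise against the genetic score
        e = e - (e @ g) / (g @ g) * g
    e = _standardize(e)
    y = np.sqrt(h2) * g + np.sqrt(1 - h2) * e
    truth.causal_gene = causal
    truth.causal_effect = float(np.sqrt(h2 * share))
    return pd.DataFrame({"accession": accs, "value": y})


def read_phenotype_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"accession", "value"} <= set(df.columns):
        raise ValueError("phenotype TSV needs 'accession' and 'value' columns")
    return df[["accession", "value"]]
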