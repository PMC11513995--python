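"""Normalisation, rarefaction and alpha-diversity metrics.

Two counts-per-million variants are supported: against the total number of
read pairs per sample (including unmapped reads) and against the number of
mapped reads only.  Rarefaction subsamples each sample's reads to a common
depth without replacement.  The diversity suite covers observed richness,
the bias-corrected Chao1 richness estimate, Pielou evenness, Shannon entropy
(nats), the Gini-Simpson index, and Hill numbers of order q = 0, 1, 2
(effective species numbers).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import AbundanceMatrix

__all__ = ["normalise", "rarefy", "diversity", "DIVERSITY_COLUMNS"]

DIVERSITY_COLUMNS = [
    "richness",
    "chao1",
    "pielou",
    "shannon",
    "simpson",
    "hill_q0",
    "hill_q1",
    "hill_q2",
]


def normalise(matrix: AbundanceMatrix, mode: str, totals: pd.Series) -> AbundanceMatrix:
    """Counts-per-million: ``counts / total * 1e6`` per sample.

    ``mode`` is ``cpm_mapped`` (totals are per-sample mapped-read counts, so
    each output row sums to exactly 1e6) or ``cpm_total`` (totals include
    unmapped reads).  A zero or missing total for any sample is an error.
    """
    if mode not in ("cpm_total", "cpm_mapped"):
        raise ValueError(f"mode must be 'cpm_total' or 'cpm_mapped', got {mode!r}")
    totals = totals.reindex(matrix.data.index)
    bad = totals.index[totals.isna() | (totals <= 0)].tolist()
    if bad:
        raise ValueError(f"zero or missing read total for samples: {bad}")
    out = matrix.data.div(totals, axis=0) * 1e6
    return AbundanceMatrix(data=out, feature_kind=matrix.feature_kind, normalisation=mode)


def rarefy(matrix: AbundanceMatrix, depth: int, seed: int) -> AbundanceMatrix:
    """Subsample each sample's reads to exactly *depth* without replacement.

    Per-sample counts are drawn from the multivariate hypergeometric
    distribution, so every rarefied row sums exactly to *depth*.  Samples with
    fewer than *depth* reads are an error (they should be removed upstream,
    as low-count samples are in practice).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if matrix.normalisation not in ("raw", "rarefied"):
        raise ValueError("rarefaction requires integer counts (raw or rarefied matrix)")
    counts = matrix.data.to_numpy().astype(np.int64)
    totals = counts.sum(axis=1)
    shallow = [sid for sid, t in zip(matrix.data.index, totals) if t < depth]
    if shallow:
        raise ValueError(f"samples with fewer than {depth} reads cannot be rarefied: {shallow}")
    rng = np.random.default_rng(seed)
    out = np.vstack([rng.multivariate_hypergeometric(row, depth) for row in counts])
    data = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return AbundanceMatrix(data=data, feature_kind=matrix.feature_kind, normalisation="rarefied")


def _profile(x: np.ndarray, chao1_variant: str) -> dict[str, float]:
    total = x.sum()
    if total == 0:
        # empty sample: zero profile, evenness undefined
        return dict.fromkeys(DIVERSITY_COLUMNS, 0.0) | {"pielou": np.nan}
    s = int((x > 0).sum())
    p = x[x > 0] / total
    shannon = float(-(p * np.log(p)).sum())
    simpson_conc = float((p**2).sum())
    simpson = 1.0 - simpson_conc
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if chao1_variant == "bias_corrected":
        chao1 = s + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    elif chao1_variant == "classic":
        chao1 = s + (f1**2 / (2.0 * f2) if f2 > 0 else f1 * (f1 - 1) / 2.0)
    else:
        raise ValueError(f"unknown chao1 variant {chao1_variant!r}")
    pielou = shannon / np.log(s) if s > 1 else np.nan
    return {
        "richness": float(s),
        "chao1": float(chao1),
        "pielou": pielou,
        "shannon": shannon,
        "simpson": simpson,
        "hill_q0": float(s),
        "hill_q1": float(np.exp(shannon)),
        "hill_q2": float(1.0 / simpson_conc),
    }


def diversity(matrix: AbundanceMatrix, chao1_variant: str = "bias_corrected") -> pd.DataFrame:
    """Per-sample alpha-diversity profile.

    Requires integer counts (Chao1 needs singleton/doubleton tallies).
    Shannon entropy uses the natural logarithm; Pielou evenness is
    ``H / ln S`` and is reported as missing for samples with a single species
    (where ``ln S = 0``).  ``hill_q1 = exp(H)`` and ``hill_q2`` is the inverse
    Simpson concentration, so ``hill_q0 >= hill_q1 >= hill_q2`` always holds.
    """
    if matrix.normalisation not in ("raw", "rarefied"):
        raise ValueError("diversity metrics require integer counts (raw or rarefied matrix)")
    counts = matrix.data.to_numpy().astype(np.int64)
    rows = [_profile(row, chao1_variant) for row in counts]
    out = pd.DataFrame(rows, index=matrix.data.index)[DIVERSITY_COLUMNS]
    out.index.name = "sample_id"
    return out
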