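"""Synthetic metagenome sample generator.

Emulates the statistical structure of a global topsoil metagenome survey so
that the whole analysis chain — annotation merging, normalisation, per-sample
taxon-function graphs, the graph regressor and its interpreter — runs end to
end without any sequence download.

Generated per configuration:

* a per-read assignment table spanning several annotation-tool dialects, with
  controlled mapped-length conflicts and ties (exercises the merge rule);
* raw species and KEGG-orthologue count matrices (samples as rows);
* a (sample, species, K-number) read-pair count table — the graph edge weights;
* sample metadata (habitat label, long-term environment features, SOC target);
* the ground truth that was planted (predictive species with association
  signs, streamlined species-function pairs, effect sizes).

The soil organic carbon target is an affine function of the realised
counts-per-million of the predictive species, a genome-streamlining presence
bonus for designated species-function pairs, a long-term temperature effect
with a negative sign, and Gaussian noise, clipped to the configured SOC range.
Species counts follow a sparse, overdispersed integer model: per-sample
relative abundances are gamma-distributed around species-specific means with
per-species zero-inflation, and counts are a multinomial draw of the sample's
sequencing depth that includes an unassigned-read category.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import ASSIGNMENT_COLUMNS, AbundanceMatrix

logger = logging.getLogger(__name__)

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_samples", "generate_read_assignments"]

HABITAT_VOCABULARY = ("boreal_forest", "temperate_forest", "grassland", "tundra", "tropical_forest")

#: Environment feature names used on habitat edges (20-year means of air
#: temperature in degC and volumetric soil water at 0-7 cm in m3 m-3).
ENV_FEATURES = ("temp_long", "soilwater_0_7_long")

#: Fraction of a sample's read pairs left unassigned by the annotation stage.
UNASSIGNED_FRACTION = 0.2

#: Gamma shape of per-sample relative-abundance fluctuations (smaller =>
#: more overdispersed, negative-binomial-like marginal counts).
ABUNDANCE_GAMMA_SHAPE = 1.5

#: Per-species probability that a non-predictive species is absent from a
#: sample (zero inflation; real soil count matrices are extremely sparse).
ZERO_INFLATION = 0.35


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the desk-scale conditions every downstream stage is tested
    under: 200 samples, 30 species of which 6 are predictive (4 positive, 2
    negative associations), two genome-streamlined species-function pairs
    absent from 30% of samples, and an SOC range matching field observations
    of 8-392 g kg^-1.
    """

    n_samples: int = 200
    n_species: int = 30
    n_functions: int = 40
    n_predictive_species: int = 6
    genome_streamline_fraction: float = 0.3
    n_streamlined_pairs: int = 2
    soc_range: tuple[float, float] = (8.0, 392.0)
    noise_sd: float = 10.0
    depth_range: tuple[int, int] = (2000, 4000)
    #: SOC shift (g kg^-1) per standard deviation of each predictive species'
    #: CPM; the sign is planted per species.
    species_effect_sd: float = 18.0
    #: SOC bonus (g kg^-1) when a streamlined pair's function is present.
    streamline_effect: float = 60.0
    #: SOC shift (g kg^-1) per SD of long-term temperature (negative: warmer
    #: long-term climate associates with lower carbon stocks).
    env_effect: float = -12.0
    baseline_soc: float = 120.0
    #: Fractions of reads given a conflicting / length-tied decoy record.
    conflict_fraction: float = 0.10
    tie_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.n_functions < 1:
            raise ValueError("n_functions must be >= 1")
        if not (1 <= self.n_predictive_species <= self.n_species):
            raise ValueError("n_predictive_species must be in [1, n_species]")
        if not (0.0 <= self.genome_streamline_fraction <= 1.0):
            raise ValueError("genome_streamline_fraction must be in [0, 1]")
        if self.n_streamlined_pairs < 0:
            raise ValueError("n_streamlined_pairs must be >= 0")
        if not (self.soc_range[0] < self.soc_range[1]):
            raise ValueError("soc_range low must be < high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.depth_range[0] <= self.depth_range[1]):
            raise ValueError("depth_range must satisfy 0 < low <= high")
        if not (0.0 <= self.conflict_fraction <= 1.0) or not (0.0 <= self.tie_fraction <= 1.0):
            raise ValueError("conflict_fraction and tie_fraction must be in [0, 1]")
        if self.conflict_fraction + self.tie_fraction > 1.0:
            raise ValueError("conflict_fraction + tie_fraction must be <= 1")


@dataclass
class SyntheticTruth:
    """Planted ground truth, for parameter-recovery tests."""

    predictive_species: list[tuple[str, int]]  # (species id, +1 | -1)
    streamlined_pairs: list[tuple[str, str]]  # (species id, K-number)
    true_effect_sizes: dict[str, float]  # "species" or "species||K" -> g kg^-1

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            predictive_species=[tuple(p) for p in raw["predictive_species"]],
            streamlined_pairs=[tuple(p) for p in raw["streamlined_pairs"]],
            true_effect_sizes=raw["true_effect_sizes"],
        )


def _species_names(n_species: int, rng: np.random.Generator) -> list[str]:
    # Binomial "Genus species" names over a small genus pool so that the
    # mid-scale genus expansion has congeners to pick up.
    n_genera = max(3, n_species // 3)
    genera = [f"Genus{i + 1:02d}" for i in range(n_genera)]
    assignment = rng.integers(0, n_genera, size=n_species)
    counters: dict[int, int] = {}
    names = []
    for g in assignment:
        counters[g] = counters.get(g, 0) + 1
        names.append(f"{genera[g]} sp{counters[g]:03d}")
    return names


def generate_samples(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, AbundanceMatrix, AbundanceMatrix, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw one synthetic cohort.

    Returns ``(read_assignments, species_matrix, function_matrix,
    pair_counts, metadata, truth)``.  Identical config and seed give
    byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n, S, F = config.n_samples, config.n_species, config.n_functions
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    species = _species_names(S, rng)
    functions = [f"K{i + 1:05d}" for i in range(F)]

    pred_idx = rng.choice(S, size=config.n_predictive_species, replace=False)
    n_neg = max(1, config.n_predictive_species // 3) if config.n_predictive_species >= 2 else 0
    signs = np.ones(config.n_predictive_species, dtype=int)
    if n_neg:
        signs[-n_neg:] = -1
    # hosts of the streamlined pairs: species with no abundance effect of
    # their own, so pair coverage is the only signal they carry
    non_pred = np.setdiff1d(np.arange(S), pred_idx)
    n_planted = min(config.n_streamlined_pairs, len(non_pred))
    host_species = np.sort(rng.choice(non_pred, size=n_planted, replace=False))

    # --- species counts: sparse overdispersed integers ----------------------
    # Gamma-Poisson mixture (negative-binomial marginals) drawn independently
    # per species so that one species' bloom does not mechanically depress the
    # others; the expected mapped fraction is 1 - UNASSIGNED_FRACTION and the
    # rare overshoot beyond the sample's depth is thinned without replacement.
    base_logmean = rng.normal(0.0, 1.0, size=S)
    rel = rng.gamma(ABUNDANCE_GAMMA_SHAPE, 1.0, size=(n, S)) * np.exp(base_logmean)
    dropout = rng.random((n, S)) < ZERO_INFLATION
    dropout[:, pred_idx] = False  # predictive species stay observable
    if n_planted:
        dropout[:, host_species] = False  # streamlined hosts stay observable
    rel[dropout] = 0.0
    expected_total = ABUNDANCE_GAMMA_SHAPE * np.exp(base_logmean).sum()
    scale = (1 - UNASSIGNED_FRACTION) / expected_total

    depth = rng.integers(config.depth_range[0], config.depth_range[1] + 1, size=n)
    counts = rng.poisson(depth[:, None] * rel * scale)
    over = counts.sum(axis=1) > depth
    for i in np.flatnonzero(over):
        counts[i] = rng.multivariate_hypergeometric(counts[i], depth[i])

    mapped_total = counts.sum(axis=1)
    # SOC is built on CPM against the sample's total read pairs: the
    # denominator is independent of every species' count, so each predictive
    # species contributes an independent signal component
    cpm = counts / depth[:, None] * 1e6

    # --- species -> function linkage profiles -------------------------------
    n_link = min(F, 6)
    link_funcs = np.vstack([rng.choice(F, size=n_link, replace=False) for _ in range(S)])
    link_weights = rng.dirichlet(np.ones(n_link), size=S) * 0.7  # 30% of reads carry no function

    # streamlined pairs: the designated function takes the dominant share of
    # its host's function-mapped reads (a highly covered gene), so its pair
    # weight has a wide dynamic range — the planted large-effect condition.
    streamlined: list[tuple[int, int]] = []
    used_funcs: set[int] = set()
    for j in range(n_planted):
        s = int(host_species[j])
        # pick the host's first linked function not already planted elsewhere,
        # so each planted pair has its own function node
        slot = 0
        for cand in range(n_link):
            if int(link_funcs[s, cand]) not in used_funcs:
                slot = cand
                break
        f = int(link_funcs[s, slot])
        used_funcs.add(f)
        streamlined.append((s, f))
        w = link_weights[s]
        w *= 0.25 / w.sum()  # sibling functions share 25%
        w[slot] = 0.45  # planted function carries 45%; 30% of reads stay unannotated
    present = rng.random((n, n_planted)) >= config.genome_streamline_fraction

    # --- pair counts ---------------------------------------------------------
    pair_rows: list[tuple[str, str, str, int]] = []
    pair_count_arr = {}  # (sample_i, species_i, func_i) -> count, for read table
    for i in range(n):
        for s in range(S):
            c = int(counts[i, s])
            if c == 0:
                continue
            w = link_weights[s].copy()
            planted_here = [(j, f) for j, (ps, f) in enumerate(streamlined) if ps == s]
            for j, f in planted_here:
                slot = int(np.where(link_funcs[s] == f)[0][0])
                if not present[i, j]:
                    w[slot] = 0.0
            w_none = max(0.0, 1.0 - w.sum())
            alloc = rng.multinomial(c, np.append(w, w_none) / (w.sum() + w_none))
            for j, f in planted_here:
                slot = int(np.where(link_funcs[s] == f)[0][0])
                if present[i, j] and alloc[slot] == 0 and alloc[-1] > 0:
                    alloc[slot] += 1  # presence implies non-zero coverage
                    alloc[-1] -= 1
            for slot in range(n_link):
                if alloc[slot] > 0:
                    fidx = int(link_funcs[s, slot])
                    pair_rows.append((sample_ids[i], species[s], functions[fidx], int(alloc[slot])))
                    pair_count_arr[(i, s, fidx)] = int(alloc[slot])
    pair_counts = pd.DataFrame(pair_rows, columns=["sample_id", "species", "function", "count"])
    pair_counts = pair_counts.sort_values(["sample_id", "species", "function"]).reset_index(drop=True)

    # --- metadata & SOC target ----------------------------------------------
    habitat = rng.choice(HABITAT_VOCABULARY, size=n)
    temp_long = rng.normal(8.0, 5.0, size=n)
    soilwater = rng.normal(0.25, 0.08, size=n).clip(0.01)

    soc = np.full(n, config.baseline_soc)
    effects: dict[str, float] = {}
    for k, s in enumerate(pred_idx):
        col = cpm[:, s]
        sd = col.std()
        coef = signs[k] * config.species_effect_sd / sd if sd > 0 else 0.0
        soc += coef * (col - col.mean())
        effects[species[int(s)]] = float(coef)
    for j, (s, f) in enumerate(streamlined):
        contrib = config.streamline_effect * present[:, j]
        soc += contrib - contrib.mean()
        effects[f"{species[s]}||{functions[f]}"] = float(config.streamline_effect)
    t_sd = temp_long.std() or 1.0
    soc += config.env_effect * (temp_long - temp_long.mean()) / t_sd
    soc += rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0

    low, high = config.soc_range
    n_clipped = int(((soc < low) | (soc > high)).sum())
    if n_clipped:
        logger.info("SOC clipped to [%s, %s] for %d of %d samples", low, high, n_clipped, n)
    soc = np.clip(soc, low, high)

    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "habitat": habitat,
            "temp_long": temp_long,
            "soilwater_0_7_long": soilwater,
            "total_reads": depth,
            "mapped_reads": mapped_total,
            "soc": soc,
        }
    ).set_index("sample_id")

    species_matrix = AbundanceMatrix(
        data=pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"), columns=species)
        .sort_index(axis=1),
        feature_kind="taxon",
    )

    reads = generate_read_assignments(species_matrix, config, pair_counts=pair_counts, rng=rng)

    func_counts = np.zeros((n, F), dtype=np.int64)
    for (i, s, fidx), c in pair_count_arr.items():
        func_counts[i, fidx] += c
    function_matrix = AbundanceMatrix(
        data=pd.DataFrame(func_counts, index=pd.Index(sample_ids, name="sample_id"), columns=functions),
        feature_kind="function",
    )

    truth = SyntheticTruth(
        predictive_species=[(species[int(s)], int(sig)) for s, sig in zip(pred_idx, signs)],
        streamlined_pairs=[(species[s], functions[f]) for s, f in streamlined],
        true_effect_sizes=effects,
    )
    return reads, species_matrix, function_matrix, pair_counts, metadata, truth


def generate_read_assignments(
    species_matrix: AbundanceMatrix,
    config: SyntheticConfig,
    pair_counts: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Expand a species count matrix into per-read annotation claims.

    Every count becomes one read record from a winning dialect.  A
    ``conflict_fraction`` subset of reads additionally receives a decoy record
    from a second dialect with a *shorter* mapped length and a different
    label; a ``tie_fraction`` subset receives a decoy of *equal* length (the
    winner is then forced to be the ``diamond`` dialect, so the documented tie
    rule reproduces the matrix).  When ``pair_counts`` is given, reads of a
    species also carry function records consistent with those pair counts.
    Re-merging the output and tabulating it reproduces ``species_matrix``
    exactly.
    """
    if species_matrix.data.size == 0:
        raise ValueError("species matrix must be non-empty")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    counts = species_matrix.data
    samples = list(counts.index)
    species = list(counts.columns)
    arr = counts.to_numpy().astype(np.int64)

    # vectorised expansion: one row per read
    i_idx, s_idx = np.nonzero(arr)
    reps = arr[i_idx, s_idx]
    read_sample = np.repeat(i_idx, reps)
    read_species = np.repeat(s_idx, reps)
    n_reads = len(read_sample)
    order = np.lexsort((read_species, read_sample))
    read_sample, read_species = read_sample[order], read_species[order]
    # per-sample running read number
    read_no = np.arange(n_reads) - np.concatenate(([0], np.cumsum(np.bincount(read_sample, minlength=len(samples)))))[read_sample]
    read_ids = np.array([f"{samples[i]}_r{j:06d}" for i, j in zip(read_sample, read_no)])

    u = rng.random(n_reads)
    is_tie = u < config.tie_fraction
    is_conflict = (u >= config.tie_fraction) & (u < config.tie_fraction + config.conflict_fraction)
    winner_len = rng.integers(100, 251, size=n_reads)
    winner_source = np.where(is_tie, "diamond", np.where(rng.random(n_reads) < 0.5, "kraken2", "diamond"))

    labels = np.array(species, dtype=object)[read_species]
    frames = [
        pd.DataFrame(
            {
                "read_id": read_ids,
                "sample_id": np.array(samples, dtype=object)[read_sample],
                "source": winner_source,
                "kind": "taxon",
                "label": labels,
                "mapped_length": winner_len,
            }
        )
    ]

    n_species = len(species)
    if n_species > 1 and (is_tie.any() or is_conflict.any()):
        decoy_species = (read_species + 1 + rng.integers(0, n_species - 1, size=n_reads)) % n_species
        decoy_labels = np.array(species, dtype=object)[decoy_species]
        sample_arr = np.array(samples, dtype=object)
        # Tie decoys: equal length from kraken2 — the diamond winner prevails
        # only through the documented tie rule.  Conflict decoys: strictly
        # shorter mapping from the dialect the winner did not use.
        if is_tie.any():
            frames.append(
                pd.DataFrame(
                    {
                        "read_id": read_ids[is_tie],
                        "sample_id": sample_arr[read_sample[is_tie]],
                        "source": "kraken2",
                        "kind": "taxon",
                        "label": decoy_labels[is_tie],
                        "mapped_length": winner_len[is_tie],
                    }
                )
            )
        if is_conflict.any():
            decoy_source = np.where(winner_source == "kraken2", "diamond", "kraken2")
            short_len = np.maximum(winner_len - rng.integers(10, 60, size=n_reads), 30)
            frames.append(
                pd.DataFrame(
                    {
                        "read_id": read_ids[is_conflict],
                        "sample_id": sample_arr[read_sample[is_conflict]],
                        "source": decoy_source[is_conflict],
                        "kind": "taxon",
                        "label": decoy_labels[is_conflict],
                        "mapped_length": short_len[is_conflict],
                    }
                )
            )

    # function records consistent with the pair-count table
    if pair_counts is not None and len(pair_counts):
        func_frames = []
        sample_pos = {sid: i for i, sid in enumerate(samples)}
        species_pos = {sp: j for j, sp in enumerate(species)}
        # index of first read per (sample, species) block (reads are lexsorted)
        change = np.flatnonzero(
            (np.diff(read_sample, prepend=-1) != 0) | (np.diff(read_species, prepend=-1) != 0)
        )
        cursor = {
            (int(read_sample[k]), int(read_species[k])): int(k) for k in change
        }
        fr_read, fr_sample, fr_label, fr_len, fr_src = [], [], [], [], []
        for row in pair_counts.itertuples(index=False):
            i = sample_pos[row.sample_id]
            s = species_pos[row.species]
            start = cursor[(i, s)]
            for k in range(start, start + row.count):
                fr_read.append(read_ids[k])
                fr_sample.append(row.sample_id)
                fr_label.append(row.function)
            cursor[(i, s)] = start + row.count
        if fr_read:
            m = len(fr_read)
            func_frames.append(
                pd.DataFrame(
                    {
                        "read_id": fr_read,
                        "sample_id": fr_sample,
                        "source": rng.choice(["diamond", "humann3"], size=m),
                        "kind": "function",
                        "label": fr_label,
                        "mapped_length": rng.integers(80, 251, size=m),
                    }
                )
            )
        frames.extend(func_frames)

    out = pd.concat(frames, ignore_index=True)[ASSIGNMENT_COLUMNS]
    out = out.sort_values(["sample_id", "read_id", "kind", "source"]).reset_index(drop=True)
    return out
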