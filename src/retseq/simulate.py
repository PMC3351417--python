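"""Synthetic data with planted truth for every downstream stage.

The generator emulates the study design the pipeline targets: four groups
(nondiabetic N, diabetic D, and diabetic treated with a RAGE inhibitor
D_T1 or a p38 MAPK inhibitor D_T2) with three biological replicates each,
negative-binomial transcript counts, exon counts as a length-proportional
multinomial split of the transcript count (so exon sums are conserved
exactly), and junction counts tied to exon depth through a fixed effective
junction-span length.  Library sizes default to 1e6 reads per sample, a
scaled stand-in for real retinal libraries in the tens of millions.

Planted effects:

* differential expression -- a fraction of transcripts get a disease
  log2 fold change drawn from a grid, with random sign;
* treatment patterns -- multiplicative on the disease effect:
  ``full_reversal`` (treated log2fc = 0), ``partial_reversal`` (0.4x),
  ``exacerbation`` (1.6x), ``none`` (unchanged by therapy), and
  ``side_effect_only`` (no disease effect, treated effect from the grid);
* cassette-exon events -- a subset of multi-exon transcripts carry a
  skipped exon whose inclusion fraction shifts between groups by a
  planted delta-I, with reversal/exacerbation patterns per treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .models import (
    GROUPS,
    CountTable,
    GeneModel,
    ReciprocalEvent,
    ReciprocalPairCatalog,
    SampleDesign,
    ValidationError,
    exon_feature_id,
    junction_feature_id,
)

DE_PATTERNS = ("null", "disease_up", "disease_down")
TREATMENT_PATTERNS = (
    "full_reversal",
    "partial_reversal",
    "exacerbation",
    "side_effect_only",
    "none",
)
PATTERN_MULTIPLIER = {
    "full_reversal": 0.0,
    "partial_reversal": 0.4,
    "exacerbation": 1.6,
    "none": 1.0,
}
EVENT_PATTERNS = ("reversal", "none", "exacerbation")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator."""

    n_transcripts: int = 2000
    n_replicates: int = 3
    library_size: int = 1_000_000
    fraction_de: float = 0.1
    fraction_side_effect: float = 0.05
    log2fc_grid: tuple[float, ...] = (0.585, 1.0, 2.0, 4.3)
    dispersion: float = 0.05
    n_cassette_events: int = 100
    delta_i_grid: tuple[float, ...] = (0.2, 0.3, 0.4)
    fraction_null_events: float = 0.5
    junction_span: int = 50
    exon_count_range: tuple[int, int] = (2, 12)
    exon_length_range: tuple[int, int] = (50, 300)
    base_log2_rpkm_mean: float = 5.5
    base_log2_rpkm_sd: float = 1.7
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ValidationError("n_transcripts must be >= 1")
        for frac in (self.fraction_de, self.fraction_side_effect, self.fraction_null_events):
            if not 0 <= frac <= 1:
                raise ValidationError("fractions must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        if any(abs(d) > 1 for d in self.delta_i_grid):
            raise ValidationError("planted |delta_I| must be <= 1")
        if self.n_replicates < 2:
            raise ValidationError("any test downstream needs >= 2 replicates per group")


@dataclass
class TruthLedger:
    """Planted ground truth: per-transcript effects and per-event inclusion.

    ``transcripts`` (indexed by transcript id): base_expression (mean RPKM
    scale), dispersion, de_pattern, disease_log2fc, pattern_T1/t1_log2fc,
    pattern_T2/t2_log2fc.  ``events`` (indexed by event id): transcript_id,
    i_N, i_D, i_T1, i_T2, delta_i_D (= i_D - i_N), pattern_T1, pattern_T2.
    """

    transcripts: pd.DataFrame
    events: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.transcripts
        if (t["dispersion"] <= 0).any():
            raise ValidationError("dispersion must be positive for every transcript")
        side = (t["pattern_T1"] == "side_effect_only") | (t["pattern_T2"] == "side_effect_only")
        if (t.loc[side, "de_pattern"] != "null").any():
            raise ValidationError("side_effect_only implies a null disease pattern")
        if len(self.events):
            deltas = self.events["delta_i_D"].abs()
            if (deltas > 1).any():
                raise ValidationError("planted |delta_I| must be <= 1")

    def group_log2fc(self) -> pd.DataFrame:
        """Planted log2 fold change vs N for every transcript and group."""
        t = self.transcripts
        return pd.DataFrame(
            {
                "N": 0.0,
                "D": t["disease_log2fc"],
                "D_T1": t["t1_log2fc"],
                "D_T2": t["t2_log2fc"],
            },
            index=t.index,
        )

    def event_inclusion(self) -> pd.DataFrame:
        """Planted inclusion fraction per event and group."""
        return self.events[["i_N", "i_D", "i_T1", "i_T2"]].rename(
            columns={"i_N": "N", "i_D": "D", "i_T1": "D_T1", "i_T2": "D_T2"}
        )


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def generate_gene_models(
    config: SimConfig, seed: int
) -> tuple[list[GeneModel], ReciprocalPairCatalog]:
    """Random transcript models plus a reciprocal-pair catalog.

    Each transcript gets 2-12 exons of 50-300 bases on a single synthetic
    chromosome; ``n_cassette_events`` transcripts with at least three
    exons are designated cassette carriers, registering their two flanking
    (inclusion) junctions and the skip (exclusion) junction.  Deterministic
    given the seed.
    """
    rng = np.random.default_rng(seed)
    lo_n, hi_n = config.exon_count_range
    lo_len, hi_len = config.exon_length_range
    models: list[GeneModel] = []
    cursor = 10_000
    for i in range(config.n_transcripts):
        n_exons = int(rng.integers(lo_n, hi_n + 1))
        lengths = rng.integers(lo_len, hi_len + 1, size=n_exons)
        introns = rng.integers(200, 2001, size=max(n_exons - 1, 0))
        exons = []
        pos = cursor
        for k in range(n_exons):
            exons.append((pos, pos + int(lengths[k])))
            pos += int(lengths[k])
            if k < n_exons - 1:
                pos += int(introns[k])
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(
            GeneModel(
                gene_id=f"G{i:05d}",
                transcript_id=f"TX{i:05d}",
                chrom="chrS",
                strand=strand,
                exons=tuple(exons),
            )
        )
        cursor = pos + 10_000

    eligible = [i for i, m in enumerate(models) if len(m.exons) >= 3]
    if config.n_cassette_events > len(eligible):
        raise ValidationError(
            f"cannot place {config.n_cassette_events} cassette events on "
            f"{len(eligible)} transcripts with >= 3 exons"
        )
    carriers = sorted(rng.choice(eligible, size=config.n_cassette_events, replace=False))
    events = []
    for e, idx in enumerate(carriers):
        m = models[idx]
        cassette = int(rng.integers(1, len(m.exons) - 1))
        jids = m.junction_ids()
        skip = junction_feature_id(m.chrom, m.exons[cassette - 1][1], m.exons[cassette + 1][0])
        events.append(
            ReciprocalEvent(
                event_id=f"EV{e:04d}",
                gene_id=m.gene_id,
                inclusion_junctions=(jids[cassette - 1], jids[cassette]),
                exclusion_junctions=(skip,),
            )
        )
    return models, ReciprocalPairCatalog(events)


# ---------------------------------------------------------------------------
# truth planting
# ---------------------------------------------------------------------------


def plant_truth(
    models: Sequence[GeneModel],
    catalog: ReciprocalPairCatalog,
    config: SimConfig,
    seed: int,
) -> TruthLedger:
    """Draw base expression and plant DE, treatment, and splicing effects.

    Base expression is lognormal and then normalized so that the counts it
    implies (via exon-model lengths and the RPKM definition) sum to the
    target library size in the baseline state: the ledger's
    ``base_expression`` IS the expected baseline RPKM, with no hidden
    scale between truth and simulation.
    """
    rng = np.random.default_rng(seed)
    n = len(models)
    tx_ids = [m.transcript_id for m in models]
    base = np.exp2(rng.normal(config.base_log2_rpkm_mean, config.base_log2_rpkm_sd, size=n))
    lengths_kb = np.array([m.exon_model_length for m in models]) / 1e3
    base *= 1e6 / (base * lengths_kb).sum()

    de_pattern = np.array(["null"] * n, dtype=object)
    disease = np.zeros(n)
    pattern_t1 = np.array(["none"] * n, dtype=object)
    pattern_t2 = np.array(["none"] * n, dtype=object)
    t1 = np.zeros(n)
    t2 = np.zeros(n)

    n_de = int(round(config.fraction_de * n))
    n_side = int(round(config.fraction_side_effect * n))
    # effects go to transcripts outside the extreme-abundance tail: the
    # handful of dominant transcripts are kept stable so planted changes
    # do not swamp library composition
    ceiling = np.quantile(base, 0.98) if n > 50 else np.inf
    eligible = np.flatnonzero(base <= ceiling)
    perm = eligible[rng.permutation(len(eligible))]
    de_idx, side_idx = perm[:n_de], perm[n_de : n_de + n_side]

    grid = np.asarray(config.log2fc_grid)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    disease[de_idx] = rng.choice(grid, size=n_de) * signs
    de_pattern[de_idx] = np.where(disease[de_idx] > 0, "disease_up", "disease_down")
    reversible = ("full_reversal", "partial_reversal", "exacerbation", "none")
    for target, patterns in ((t1, pattern_t1), (t2, pattern_t2)):
        chosen = rng.choice(len(reversible), size=n_de)
        patterns[de_idx] = np.asarray(reversible, dtype=object)[chosen]
        mult = np.array([PATTERN_MULTIPLIER[reversible[c]] for c in chosen])
        target[de_idx] = disease[de_idx] * mult

    # side-effect-only transcripts: no disease change, one therapy moves them
    which = rng.choice([0, 1], size=n_side)
    effect = rng.choice(grid, size=n_side) * rng.choice([-1.0, 1.0], size=n_side)
    for k, i in enumerate(side_idx):
        if which[k] == 0:
            pattern_t1[i] = "side_effect_only"
            t1[i] = effect[k]
        else:
            pattern_t2[i] = "side_effect_only"
            t2[i] = effect[k]

    transcripts = pd.DataFrame(
        {
            "base_expression": base,
            "dispersion": config.dispersion,
            "de_pattern": de_pattern,
            "disease_log2fc": disease,
            "pattern_T1": pattern_t1,
            "t1_log2fc": t1,
            "pattern_T2": pattern_t2,
            "t2_log2fc": t2,
        },
        index=pd.Index(tx_ids, name="transcript_id"),
    )

    gene_to_tx = {m.gene_id: m.transcript_id for m in models}
    ev_rows = []
    n_events = len(catalog)
    n_null = int(round(config.fraction_null_events * n_events))
    null_flags = np.zeros(n_events, dtype=bool)
    null_flags[rng.permutation(n_events)[:n_null]] = True
    for flag_null, ev in zip(null_flags, catalog):
        if flag_null:
            i_n = i_d = i_t1 = i_t2 = 0.5
            p1 = p2 = "none"
            delta = 0.0
        else:
            delta = float(rng.choice(config.delta_i_grid) * rng.choice([-1.0, 1.0]))
            i_n = 0.5 - delta / 2
            i_d = 0.5 + delta / 2
            p1, p2 = rng.choice(EVENT_PATTERNS, size=2)
            lookup = {"reversal": i_n, "none": i_d,
                      "exacerbation": float(np.clip(i_n + 1.6 * delta, 0.02, 0.98))}
            i_t1, i_t2 = lookup[p1], lookup[p2]
        ev_rows.append(
            {
                "event_id": ev.event_id,
                "transcript_id": gene_to_tx[ev.gene_id],
                "i_N": i_n,
                "i_D": i_d,
                "i_T1": i_t1,
                "i_T2": i_t2,
                "delta_i_D": delta,
                "pattern_T1": p1,
                "pattern_T2": p2,
            }
        )
    events = (
        pd.DataFrame(ev_rows).set_index("event_id")
        if ev_rows
        else pd.DataFrame(
            columns=["transcript_id", "i_N", "i_D", "i_T1", "i_T2",
                     "delta_i_D", "pattern_T1", "pattern_T2"]
        )
    )
    return TruthLedger(transcripts, events)


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """NB draw parameterized by mean and dispersion (var = mu + phi*mu^2)."""
    mean = np.maximum(mean, 1e-12)
    r = 1.0 / np.maximum(dispersion, 1e-12)
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    models: Sequence[GeneModel],
    catalog: ReciprocalPairCatalog,
    design: SampleDesign,
    truth: TruthLedger,
    config: SimConfig,
    seed: int,
) -> tuple[CountTable, CountTable, CountTable]:
    """Draw (exon, junction, transcript) count tables from the planted truth.

    Transcript counts are negative binomial with mean given directly by
    the RPKM definition: C = base_RPKM x 2^(group log2fc) x L_kb x N/1e6.
    The depth N is deliberately the same nominal constant for every group:
    renormalizing each group's realized total to one target would shift
    every null transcript between groups (a composition artifact) and
    contradict the planted truth.  ``library_sizes`` carries that nominal
    depth, so RPKM of null transcripts is unbiased across groups and the
    baseline column sums match the target by construction.  Exon counts are an exact multinomial split
    of the transcript count by exon length.  Junction counts are Poisson
    with mean ``transcript_count * span / L``; for cassette events the two
    inclusion junctions are thinned by the group's planted inclusion
    fraction and the skip junction by its complement.
    """
    models = list(models)
    tx_ids = [m.transcript_id for m in models]
    missing = set(tx_ids) - set(truth.transcripts.index)
    if missing:
        raise ValidationError(f"truth ledger missing transcript(s): {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)

    lengths = np.array([m.exon_model_length for m in models], dtype=float)
    base = truth.transcripts.loc[tx_ids, "base_expression"].to_numpy()
    dispersion = truth.transcripts.loc[tx_ids, "dispersion"].to_numpy()
    lfc = truth.group_log2fc().loc[tx_ids]

    base_counts = base * lengths / 1e3  # expected counts before library scaling
    sample_groups = dict(zip(design.table["sample_id"], design.table["group"]))
    sample_ids = design.sample_ids

    # expected counts straight from the RPKM definition: C = RPKM * L_kb * N/1e6
    mu = np.empty((len(models), len(sample_ids)))
    for j, s in enumerate(sample_ids):
        g = sample_groups[s]
        mu[:, j] = base_counts * np.exp2(lfc[g].to_numpy()) * (config.library_size / 1e6)

    tx_counts = _nb_draw(rng, mu, dispersion[:, None])
    transcript_table = pd.DataFrame(
        tx_counts, index=pd.Index(tx_ids, name="transcript_id"), columns=sample_ids
    )
    # nominal depth, shared by all samples: the quantity the scaling targets
    library_sizes = pd.Series(config.library_size, index=sample_ids)

    # exon counts: exact multinomial split by exon length
    exon_ids: list[str] = []
    exon_rows: list[np.ndarray] = []
    for i, m in enumerate(models):
        probs = np.array([e - s for s, e in m.exons], dtype=float)
        probs /= probs.sum()
        draws = np.stack(
            [rng.multinomial(int(tx_counts[i, j]), probs) for j in range(len(sample_ids))],
            axis=1,
        )
        exon_ids.extend(m.exon_ids())
        exon_rows.append(draws)
    exon_table = pd.DataFrame(
        np.concatenate(exon_rows, axis=0),
        index=pd.Index(exon_ids, name="exon_id"),
        columns=sample_ids,
    )

    # junction means: span/L of the carrying transcript, thinned by the
    # planted inclusion fraction on cassette-event junctions
    inclusion_of = truth.event_inclusion()
    special: dict[str, np.ndarray] = {}
    group_per_sample = np.array([sample_groups[s] for s in sample_ids])
    for ev in catalog:
        psi_by_group = inclusion_of.loc[ev.event_id]
        psi = np.array([psi_by_group[g] for g in group_per_sample])
        for j in ev.inclusion_junctions:
            special[j] = psi
        for j in ev.exclusion_junctions:
            special[j] = 1.0 - psi
    events_by_gene: dict[str, list[ReciprocalEvent]] = {}
    for ev in catalog:
        events_by_gene.setdefault(ev.gene_id, []).append(ev)
    jn_ids: list[str] = []
    jn_mean_rows: list[np.ndarray] = []
    tx_index = {tid: i for i, tid in enumerate(tx_ids)}
    seen: set[str] = set()
    for m in models:
        i = tx_index[m.transcript_id]
        base_mean = tx_counts[i].astype(float) * config.junction_span / lengths[i]
        for jid in m.junction_ids():
            if jid in seen:
                continue
            seen.add(jid)
            factor = special.get(jid, np.ones(len(sample_ids)))
            jn_ids.append(jid)
            jn_mean_rows.append(base_mean * factor)
        for ev in events_by_gene.get(m.gene_id, []):
            for jid in ev.exclusion_junctions:
                if jid in seen:
                    continue
                seen.add(jid)
                jn_ids.append(jid)
                jn_mean_rows.append(base_mean * special[jid])
    jn_counts = rng.poisson(np.stack(jn_mean_rows)) if jn_mean_rows else np.zeros((0, len(sample_ids)), dtype=int)
    junction_table = pd.DataFrame(
        jn_counts, index=pd.Index(jn_ids, name="junction_id"), columns=sample_ids
    )

    transcript_ct = CountTable(transcript_table, library_sizes, "transcript")
    exon_ct = CountTable(exon_table, library_sizes, "exon")
    junction_ct = CountTable(junction_table, library_sizes, "junction")
    return exon_ct, junction_ct, transcript_ct


@dataclass
class SimulatedDataset:
    """Everything one simulation run produces."""

    config: SimConfig
    models: list[GeneModel]
    catalog: ReciprocalPairCatalog
    design: SampleDesign
    truth: TruthLedger
    exon_counts: CountTable
    junction_counts: CountTable
    transcript_counts: CountTable


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator from a single master seed.

    Stage seeds are spawned deterministically from ``config.seed`` so each
    stage is reproducible in isolation.
    """
    ss = np.random.SeedSequence(config.seed)
    s_models, s_truth, s_counts = [int(x % (2**31)) for x in ss.generate_state(3)]
    models, catalog = generate_gene_models(config, s_models)
    truth = plant_truth(models, catalog, config, s_truth)
    design = SampleDesign.balanced(config.n_replicates)
    exon_ct, junction_ct, transcript_ct = simulate_counts(
        models, catalog, design, truth, config, s_counts
    )
    return SimulatedDataset(
        config, models, catalog, design, truth, exon_ct, junction_ct, transcript_ct
    )
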