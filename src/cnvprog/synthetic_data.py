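"""Synthetic aCGH cohort generator.

Emulates the data structure of a multicentric pituitary-tumor copy-number
study: five tumor lineages with very different genomic-instability burdens,
an excess of gains over losses, occasional copy-neutral LOH, clinical
covariates (grade, age, sex, size, secretion, GNAS/USP8 status) and a
5-year recurrence outcome drawn from a logistic model in which instability
burden carries prognostic information in lactotroph tumors only.

Every generator is deterministic under a fixed seed. CNV events are laid
down in probe-index space (each event starts and ends exactly on probes),
so the true altered-probe fraction is exact and noise-free profiles can be
recovered perfectly by the segmentation pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .genome import GenomeSpec, InvalidConfigError, ProbeMap, hg19_autosomes

__all__ = [
    "TypeParams",
    "CohortConfig",
    "CNVEvent",
    "LOHEvent",
    "SampleTruth",
    "TruthSet",
    "generate_cohort_truth",
    "simulate_l2r_profiles",
    "simulate_homozygosity",
    "make_gene_annotation",
    "simulate_expression",
]

TUMOR_TYPES = ["gonadotroph", "immunonegative", "somatotroph", "lactotroph", "corticotroph"]


@dataclass(frozen=True)
class TypeParams:
    """Per-lineage cohort composition and burden-distribution parameters.

    ``median_altered`` is the marginal target median of the altered-probe
    fraction across tumors of this type (zero-burden tumors included);
    ``p_altered`` is the probability of carrying at least one CNV. When
    more than half the tumors are CNV-free the marginal median is 0 by
    construction and ``cond_median`` pins the location of the non-zero
    burden distribution instead.
    """

    n: int
    p_altered: float
    median_altered: float
    max_altered: float
    cond_median: float
    burden_sigma: float
    gain_share: float
    recurrence_rate: float
    loh_prob: float

    def __post_init__(self) -> None:
        if self.n < 0:
            raise InvalidConfigError("sample count must be >= 0")
        for name in ("p_altered", "median_altered", "max_altered", "cond_median",
                     "gain_share", "recurrence_rate", "loh_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} outside [0, 1]")


def _default_type_params() -> dict[str, TypeParams]:
    # Cohort sizes, altered-tumor counts, burden medians/maxima, recurrence
    # rates and LOH frequencies follow the study cohort this generator
    # emulates; gain shares reflect the reported gain excess per lineage.
    return {
        "gonadotroph": TypeParams(56, 24 / 56, 0.000, 0.097, 0.020, 1.0, 0.70, 33 / 56, 13 / 56),
        "immunonegative": TypeParams(11, 2 / 11, 0.000, 0.165, 0.030, 1.0, 0.50, 5 / 11, 2 / 11),
        "somatotroph": TypeParams(56, 37 / 56, 0.048, 0.998, 0.150, 1.8, 0.80, 40 / 56, 17 / 56),
        "lactotroph": TypeParams(39, 34 / 39, 0.383, 0.967, 0.450, 1.5, 0.90, 28 / 39, 15 / 39),
        "corticotroph": TypeParams(33, 24 / 33, 0.111, 0.766, 0.215, 1.6, 0.70, 18 / 33, 9 / 33),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Full generative configuration for a synthetic cohort.

    Recurrence model (log odds):
      intercept(type) + beta_grade(grade) + beta_age * (age - 47.1)/10
      + beta_burden * log2(altered probe count + 1)  [lactotroph only]
    with per-type intercepts solved so each lineage hits its target
    recurrence rate. Odds-ratio parameters are expressed on the scale the
    analysis reports: per grade level vs 1a, per 10 years of age, and per
    doubling of altered probes.
    """

    type_params: dict[str, TypeParams] = field(default_factory=_default_type_params)
    # event-scope mixture: whole chromosome / whole arm / focal
    p_whole_chrom: float = 0.35
    p_whole_arm: float = 0.20
    focal_mb_range: tuple[float, float] = (1.0, 20.0)
    min_event_probes: int = 5
    # minimum copy-neutral probes left between distinct events, so that
    # every neutral gap is wide enough to be isolated by segmentation
    min_event_gap_probes: int = 3
    # recurrence model
    or_grade_1b: float = 1.5
    or_grade_2a: float = 4.3
    or_grade_2b: float = 8.7
    or_age_per_10y: float = 0.6
    or_sex_male: float = 1.0
    or_burden_lactotroph: float = 1.3  # per doubling of altered probes
    mean_age: float = 47.1
    sd_age: float = 14.3
    p_female: float = 0.431
    grade_probs: tuple[float, float, float, float] = (0.319, 0.046, 0.456, 0.179)
    size_probs: tuple[float, float, float] = (0.067, 0.892, 0.041)
    # measurement model defaults
    noise_sd: float = 0.15
    purity: float = 1.0
    snp_fraction: float = 0.15
    loh_mb_range: tuple[float, float] = (10.0, 30.0)
    baseline_hom_prob: float = 0.65

    def __post_init__(self) -> None:
        for t, p in self.type_params.items():
            if t not in TUMOR_TYPES:
                raise InvalidConfigError(f"unknown tumor type {t!r}")
            if p.max_altered > 1 or p.median_altered > 1:
                raise InvalidConfigError("burden targets must be <= 1")
        for name in ("or_grade_1b", "or_grade_2a", "or_grade_2b", "or_age_per_10y",
                     "or_sex_male", "or_burden_lactotroph"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0")
        if self.p_whole_chrom + self.p_whole_arm > 1:
            raise InvalidConfigError("event-scope probabilities exceed 1")


@dataclass(frozen=True)
class CNVEvent:
    chrom: int
    start: int          # bp, 1-based inclusive
    end: int
    state: str          # "gain" | "loss"
    probe_start: int    # global probe index, inclusive
    probe_end: int

    def __post_init__(self) -> None:
        if self.state not in ("gain", "loss"):
            raise InvalidConfigError(f"invalid CNV state {self.state!r}")


@dataclass(frozen=True)
class LOHEvent:
    chrom: int
    start: int
    end: int
    probe_start: int
    probe_end: int


@dataclass
class SampleTruth:
    sample_id: str
    tumor_type: str
    covariates: dict
    recurrence: int
    events: list[CNVEvent]
    loh_events: list[LOHEvent]
    altered_fraction: float


@dataclass
class TruthSet:
    """Ground truth for a simulated cohort: events, burdens, clinical table."""

    samples: list[SampleTruth]
    n_probes: int

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def clinical_table(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row = {"sample_id": s.sample_id, "tumor_type": s.tumor_type,
                   **s.covariates, "recurrence": s.recurrence}
            rows.append(row)
        return pd.DataFrame(rows).set_index("sample_id")

    def truth_matrix(self, probe_map: ProbeMap) -> pd.DataFrame:
        """True probe-state matrix (samples x probes, values -1/0/+1)."""
        mat = np.zeros((len(self.samples), len(probe_map)), dtype=np.int8)
        for i, s in enumerate(self.samples):
            for ev in s.events:
                mat[i, ev.probe_start : ev.probe_end + 1] = 1 if ev.state == "gain" else -1
        return pd.DataFrame(mat, index=self.sample_ids, columns=probe_map.probe_ids)

    def loh_matrix(self, probe_map: ProbeMap) -> pd.DataFrame:
        mat = np.zeros((len(self.samples), len(probe_map)), dtype=bool)
        for i, s in enumerate(self.samples):
            for ev in s.loh_events:
                mat[i, ev.probe_start : ev.probe_end + 1] = True
        return pd.DataFrame(mat, index=self.sample_ids, columns=probe_map.probe_ids)

    def to_dict(self) -> dict:
        return {
            "n_probes": self.n_probes,
            "samples": [
                {
                    "sample_id": s.sample_id,
                    "tumor_type": s.tumor_type,
                    "covariates": s.covariates,
                    "recurrence": s.recurrence,
                    "altered_fraction": s.altered_fraction,
                    "events": [asdict(e) for e in s.events],
                    "loh_events": [asdict(e) for e in s.loh_events],
                }
                for s in self.samples
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthSet":
        samples = [
            SampleTruth(
                sample_id=s["sample_id"],
                tumor_type=s["tumor_type"],
                covariates=s["covariates"],
                recurrence=int(s["recurrence"]),
                events=[CNVEvent(**e) for e in s["events"]],
                loh_events=[LOHEvent(**e) for e in s["loh_events"]],
                altered_fraction=float(s["altered_fraction"]),
            )
            for s in d["samples"]
        ]
        return cls(samples=samples, n_probes=int(d["n_probes"]))


def _target_burden(params: TypeParams, rng: np.random.Generator) -> float:
    """Draw a target altered-probe fraction for one tumor.

    Zero with probability 1 - p_altered; otherwise logit-normal, located so
    that the marginal median matches ``median_altered`` whenever fewer than
    half the tumors are CNV-free (the conditional quantile that the
    marginal median falls on is (0.5 - p0) / (1 - p0)).
    """
    if rng.random() >= params.p_altered:
        return 0.0
    p0 = 1.0 - params.p_altered
    if p0 < 0.5 and params.median_altered > 0:
        q = (0.5 - p0) / (1.0 - p0)
        mu = logit(params.median_altered) - params.burden_sigma * norm.ppf(q)
    else:
        mu = logit(params.cond_median)
    f = float(expit(rng.normal(mu, params.burden_sigma)))
    return min(f, params.max_altered)


class _FreeProbes:
    """Track unallocated probe-index ranges per chromosome."""

    def __init__(self, probe_map: ProbeMap):
        self.slices = probe_map.chrom_slices()
        self.free = {c: [(sl.start, sl.stop - 1)] for c, sl in self.slices.items()}

    def whole_chrom_candidates(self) -> list[int]:
        return [c for c, iv in self.free.items()
                if iv == [(self.slices[c].start, self.slices[c].stop - 1)]]

    def take(self, chrom: int, lo: int, hi: int, margin: int = 0) -> None:
        lo, hi = lo - margin, hi + margin
        new = []
        for a, b in self.free[chrom]:
            if hi < a or lo > b:
                new.append((a, b))
            else:
                if a < lo:
                    new.append((a, lo - 1))
                if hi < b:
                    new.append((hi + 1, b))
        self.free[chrom] = new

    def fitting_intervals(self, k: int) -> list[tuple[int, int, int]]:
        return [(c, a, b) for c, ivs in self.free.items() for a, b in ivs if b - a + 1 >= k]


def _draw_events(
    target_frac: float,
    probe_map: ProbeMap,
    genome: GenomeSpec,
    params: TypeParams,
    config: CohortConfig,
    rng: np.random.Generator,
) -> list[CNVEvent]:
    """Place CNV events until the altered-probe fraction reaches its target."""
    n_total = len(probe_map)
    target_probes = int(round(target_frac * n_total))
    if target_probes < config.min_event_probes:
        target_probes = config.min_event_probes if target_frac > 0 else 0
    pos = probe_map.pos
    mean_spacing = genome.total_length / n_total
    free = _FreeProbes(probe_map)
    slices = free.slices
    events: list[CNVEvent] = []
    covered = 0
    attempts = 0
    while covered < target_probes and attempts < 2000:
        attempts += 1
        remaining = target_probes - covered
        smallest_chrom_probes = min(sl.stop - sl.start for sl in slices.values())
        u = rng.random()
        if remaining >= smallest_chrom_probes and u < config.p_whole_chrom:
            scope = "chrom"
        elif remaining >= smallest_chrom_probes // 2 and u < config.p_whole_chrom + config.p_whole_arm:
            scope = "arm"
        else:
            scope = "focal"

        if scope == "chrom":
            cands = [c for c in free.whole_chrom_candidates()
                     if slices[c].stop - slices[c].start <= remaining * 1.6]
            if not cands:
                continue
            c = int(rng.choice(cands))
            lo, hi = slices[c].start, slices[c].stop - 1
        elif scope == "arm":
            cands = []
            for c in free.whole_chrom_candidates():
                sl = slices[c]
                cen = genome.centromeres[c]
                split = sl.start + int(np.searchsorted(pos[sl], cen, side="right"))
                for lo_, hi_ in ((sl.start, split - 1), (split, sl.stop - 1)):
                    k = hi_ - lo_ + 1
                    if k >= config.min_event_probes and k <= remaining * 1.6:
                        cands.append((c, lo_, hi_))
            if not cands:
                continue
            c, lo, hi = cands[int(rng.integers(len(cands)))]
        else:
            mb = rng.uniform(*config.focal_mb_range)
            k = max(config.min_event_probes, int(round(mb * 1e6 / mean_spacing)))
            k = min(k, max(remaining, config.min_event_probes))
            fits = free.fitting_intervals(k)
            if not fits:
                break
            c, a, b = fits[int(rng.integers(len(fits)))]
            lo = int(rng.integers(a, b - k + 2))
            hi = lo + k - 1
            # snap to the chromosome edge rather than leave a neutral sliver
            # narrower than the minimum isolatable gap
            cs, ce = slices[c].start, slices[c].stop - 1
            if a == cs and lo - cs < config.min_event_gap_probes:
                lo = cs
            if b == ce and ce - hi < config.min_event_gap_probes:
                hi = ce

        free.take(c, lo, hi, margin=config.min_event_gap_probes)
        state = "gain" if rng.random() < params.gain_share else "loss"
        events.append(CNVEvent(chrom=c, start=int(pos[lo]), end=int(pos[hi]),
                               state=state, probe_start=lo, probe_end=hi))
        covered += hi - lo + 1
    return sorted(events, key=lambda e: (e.chrom, e.start))


def _draw_loh(
    params: TypeParams,
    config: CohortConfig,
    probe_map: ProbeMap,
    genome: GenomeSpec,
    events: list[CNVEvent],
    rng: np.random.Generator,
) -> list[LOHEvent]:
    """Copy-neutral LOH intervals, placed only on CNV-free probe runs."""
    if rng.random() >= params.loh_prob:
        return []
    n_events = 1 + rng.poisson(0.7)
    mean_spacing = genome.total_length / len(probe_map)
    free = _FreeProbes(probe_map)
    for ev in events:
        free.take(ev.chrom, ev.probe_start, ev.probe_end)
    pos = probe_map.pos
    out: list[LOHEvent] = []
    for _ in range(n_events):
        mb = rng.uniform(*config.loh_mb_range)
        k = max(config.min_event_probes, int(round(mb * 1e6 / mean_spacing)))
        fits = free.fitting_intervals(k)
        if not fits:
            break
        c, a, b = fits[int(rng.integers(len(fits)))]
        lo = int(rng.integers(a, b - k + 2))
        hi = lo + k - 1
        free.take(c, lo, hi)
        out.append(LOHEvent(chrom=c, start=int(pos[lo]), end=int(pos[hi]),
                            probe_start=lo, probe_end=hi))
    return sorted(out, key=lambda e: (e.chrom, e.start))


_GRADES = ["1a", "1b", "2a", "2b"]
_SIZES = ["micro", "macro", "giant"]
_SILENT_PROB = {"gonadotroph": 1.0, "immunonegative": 1.0, "somatotroph": 0.071,
                "lactotroph": 0.051, "corticotroph": 0.242}
_GNAS_PROBS = (40 / 56, 13 / 56, 3 / 56)   # wt, mutation, NA (somatotroph only)
_USP8_PROBS = (22 / 33, 5 / 33, 6 / 33)    # wt, mutation, NA (corticotroph only)


def _draw_covariates(ttype: str, config: CohortConfig, rng: np.random.Generator) -> dict:
    age = float(np.clip(rng.normal(config.mean_age, config.sd_age), 18.0, 85.0))
    sex = "F" if rng.random() < config.p_female else "M"
    grade = _GRADES[int(rng.choice(4, p=np.asarray(config.grade_probs) / sum(config.grade_probs)))]
    size = _SIZES[int(rng.choice(3, p=np.asarray(config.size_probs) / sum(config.size_probs)))]
    secretion = "silent" if rng.random() < _SILENT_PROB[ttype] else "functioning"
    gnas = usp8 = "NA"
    if ttype == "somatotroph":
        gnas = ["wt", "mutation", "NA"][int(rng.choice(3, p=_GNAS_PROBS))]
    if ttype == "corticotroph":
        usp8 = ["wt", "mutation", "NA"][int(rng.choice(3, p=_USP8_PROBS))]
    return {"grade": grade, "age": round(age, 1), "sex": sex, "size_class": size,
            "secretion": secretion, "gnas": gnas, "usp8": usp8}


def _linear_predictor_no_intercept(
    s: SampleTruth, config: CohortConfig, n_probes: int
) -> float:
    cov = s.covariates
    eta = 0.0
    eta += {"1a": 0.0, "1b": math.log(config.or_grade_1b),
            "2a": math.log(config.or_grade_2a), "2b": math.log(config.or_grade_2b)}[cov["grade"]]
    eta += math.log(config.or_age_per_10y) * (cov["age"] - config.mean_age) / 10.0
    if cov["sex"] == "M":
        eta += math.log(config.or_sex_male)
    if s.tumor_type == "lactotroph":
        count = s.altered_fraction * n_probes
        eta += math.log(config.or_burden_lactotroph) * math.log2(count + 1.0)
    return eta


def generate_cohort_truth(
    config: CohortConfig,
    probe_map: ProbeMap,
    seed: int = 0,
    genome: GenomeSpec | None = None,
) -> TruthSet:
    """Simulate a cohort: CNV/LOH truth, covariates and recurrence labels.

    Per-type intercepts of the recurrence model are solved numerically so
    that the expected recurrence rate of each lineage (averaged over its
    drawn covariates and burdens) equals the configured target; labels are
    then Bernoulli draws from the per-sample probabilities.
    """
    if len(probe_map) == 0:
        raise InvalidConfigError("probe map is empty")
    genome = genome or hg19_autosomes()
    rng = np.random.default_rng(seed)
    n_probes = len(probe_map)
    samples: list[SampleTruth] = []
    for ttype in TUMOR_TYPES:
        params = config.type_params.get(ttype)
        if params is None or params.n == 0:
            continue
        for i in range(params.n):
            target = _target_burden(params, rng)
            events = _draw_events(target, probe_map, genome, params, config, rng)
            loh = _draw_loh(params, config, probe_map, genome, events, rng)
            covered = sum(e.probe_end - e.probe_start + 1 for e in events)
            cov = _draw_covariates(ttype, config, rng)
            samples.append(SampleTruth(
                sample_id=f"{ttype[:4].upper()}_{i + 1:04d}",
                tumor_type=ttype,
                covariates=cov,
                recurrence=0,  # assigned below
                events=events,
                loh_events=loh,
                altered_fraction=covered / n_probes,
            ))

    # per-type intercepts: solve mean(expit(a + eta_i)) = target rate
    for ttype in TUMOR_TYPES:
        group = [s for s in samples if s.tumor_type == ttype]
        if not group:
            continue
        target_rate = config.type_params[ttype].recurrence_rate
        etas = np.array([_linear_predictor_no_intercept(s, config, n_probes) for s in group])

        def gap(a: float) -> float:
            return float(np.mean(expit(a + etas))) - target_rate

        intercept = brentq(gap, -30.0, 30.0)
        probs = expit(intercept + etas)
        draws = rng.random(len(group))
        for s, p, u in zip(group, probs, draws):
            s.recurrence = int(u < p)
    return TruthSet(samples=samples, n_probes=n_probes)


_LOG2_HALF = math.log2(0.5)


def dosage_l2r(state: int, purity: float = 1.0) -> float:
    """Expected log2 ratio of a single-copy event at the given tumor purity."""
    return math.log2((2.0 + purity * state) / 2.0)


def simulate_l2r_profiles(
    truth: TruthSet,
    probe_map: ProbeMap,
    noise_sd: float = 0.15,
    purity: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Forward model of the measured log2 ratios (probes x samples).

    Probe mean is log2((2 + purity * delta_copies) / 2) inside true events
    (+-1 copy) and 0 elsewhere; i.i.d. Gaussian noise of ``noise_sd`` log2
    units is added. cnLOH leaves the log2 ratio untouched (it is copy
    neutral); it is visible only in the homozygosity channel.
    """
    if noise_sd < 0:
        raise InvalidConfigError("noise_sd must be >= 0")
    if not 0 < purity <= 1:
        raise InvalidConfigError("purity must be in (0, 1]")
    for s in truth.samples:
        for ev in s.events:
            if ev.probe_end >= len(probe_map):
                raise InvalidConfigError(
                    f"event on sample {s.sample_id} outside probe map")
    rng = np.random.default_rng(seed)
    gain = dosage_l2r(+1, purity)
    loss = dosage_l2r(-1, purity)
    mat = np.zeros((len(probe_map), len(truth.samples)))
    for j, s in enumerate(truth.samples):
        for ev in s.events:
            mat[ev.probe_start : ev.probe_end + 1, j] = gain if ev.state == "gain" else loss
    if noise_sd > 0:
        mat += rng.normal(0.0, noise_sd, size=mat.shape)
    return pd.DataFrame(mat, index=probe_map.probe_ids, columns=truth.sample_ids)


def simulate_homozygosity(
    truth: TruthSet,
    probe_map: ProbeMap,
    baseline_hom_prob: float = 0.65,
    seed: int = 0,
) -> pd.DataFrame:
    """Boolean homozygosity calls on SNP probes (SNP probes x samples).

    Outside LOH each SNP probe is homozygous independently with the
    population baseline probability; inside cnLOH intervals and one-copy
    deletions the locus is effectively monoallelic and reads homozygous.
    """
    rng = np.random.default_rng(seed)
    snp_idx = np.flatnonzero(probe_map.is_snp)
    hom = rng.random((len(snp_idx), len(truth.samples))) < baseline_hom_prob
    lookup = {g: i for i, g in enumerate(snp_idx)}
    for j, s in enumerate(truth.samples):
        intervals = [(e.probe_start, e.probe_end) for e in s.loh_events]
        intervals += [(e.probe_start, e.probe_end) for e in s.events if e.state == "loss"]
        for lo, hi in intervals:
            a = np.searchsorted(snp_idx, lo, side="left")
            b = np.searchsorted(snp_idx, hi, side="right")
            hom[a:b, j] = True
    ids = probe_map.probe_ids[snp_idx]
    return pd.DataFrame(hom, index=ids, columns=truth.sample_ids)


def make_gene_annotation(
    genome: GenomeSpec | None = None,
    n_genes: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Random gene intervals across the autosomes (1-based inclusive).

    Gene counts per chromosome are proportional to length; lengths are
    log-uniform between 5 kb and 1.5 Mb, roughly the span of human genes.
    Returns a frame with columns gene, chrom, start, end, sorted.
    """
    genome = genome or hg19_autosomes()
    rng = np.random.default_rng(seed)
    chroms = genome.chromosomes
    lens = np.array([genome.lengths[c] for c in chroms], dtype=float)
    counts = np.maximum(1, np.round(lens / lens.sum() * n_genes).astype(int))
    rows = []
    for c, L, k in zip(chroms, lens, counts):
        glen = np.exp(rng.uniform(np.log(5e3), np.log(1.5e6), size=k)).astype(np.int64)
        start = (rng.random(k) * (L - glen - 1)).astype(np.int64) + 1
        rows.append(pd.DataFrame({"chrom": c, "start": start, "end": start + glen - 1}))
    ann = pd.concat(rows, ignore_index=True).sort_values(["chrom", "start"], kind="stable")
    ann = ann.reset_index(drop=True)
    ann.insert(0, "gene", [f"G{i + 1:05d}" for i in range(len(ann))])
    return ann


class UnknownGeneError(KeyError):
    """Raised when a designated DE gene is absent from the annotation."""


def simulate_expression(
    truth: TruthSet,
    gene_annotation: pd.DataFrame,
    de_genes: dict[str, float] | None = None,
    seed: int = 0,
    baseline_log2_mean: float = 7.0,
    baseline_log2_sd: float = 1.5,
    noise_log2_sd: float = 0.4,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Dosage-linked expression matrix (genes x samples, linear scale).

    Baseline expression is log-normal per gene; genes inside gained/lost
    regions are scaled by the copy-dosage factor (3/2 or 1/2); genes in
    ``de_genes`` (gene -> fold change, > 0) are additionally scaled by
    their effect in recurrent samples (fold changes < 1 model
    down-regulation).
    """
    de_genes = de_genes or {}
    if (gene_annotation["end"] < gene_annotation["start"]).any():
        raise InvalidConfigError("gene annotation has end < start")
    unknown = set(de_genes) - set(gene_annotation["gene"])
    if unknown:
        raise UnknownGeneError(f"de_genes not in annotation: {sorted(unknown)}")
    for fc in de_genes.values():
        if fc <= 0:
            raise InvalidConfigError("effect sizes must be > 0")
    rng = np.random.default_rng(seed)
    keep = truth.samples if samples is None else [
        s for s in truth.samples if s.sample_id in set(samples)]
    genes = gene_annotation["gene"].to_numpy()
    n_g, n_s = len(genes), len(keep)
    base = rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_g)
    log2e = np.tile(base[:, None], (1, n_s))

    g_chrom = gene_annotation["chrom"].to_numpy()
    g_start = gene_annotation["start"].to_numpy()
    g_end = gene_annotation["end"].to_numpy()
    for j, s in enumerate(keep):
        for ev in s.events:
            # dosage applies to genes overlapping the event at all
            sel = (g_chrom == ev.chrom) & (g_start <= ev.end) & (g_end >= ev.start)
            log2e[sel, j] += math.log2(1.5) if ev.state == "gain" else _LOG2_HALF
        if s.recurrence:
            for g, fc in de_genes.items():
                log2e[genes == g, j] += math.log2(fc)
    log2e += rng.normal(0.0, noise_log2_sd, size=log2e.shape)
    return pd.DataFrame(2.0 ** log2e, index=pd.Index(genes, name="gene"),
                        columns=[s.sample_id for s in keep])
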