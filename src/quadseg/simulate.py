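"""Synthetic PGT-SR cohort generator.

Emulates the statistical structure the analysis assumes: carriers with a
reciprocal-translocation karyotype drawn from the autosomes, a clutch of
diagnosed blastocysts per carrier, a per-carrier random intercept shared
by all non-alternate contrasts (clustered outcomes), segregation modes
drawn from a multinomial logit on carrier covariates, and CNV profiles
emitted from the corresponding embryo signatures with boundary jitter,
incidental whole-chromosome aneuploidy, and a fraction of uninterpretable
(ND) profiles simulated as spurious-segment corruption.

Default rates and effect sizes are the published cohort's: marginal mode
frequencies 46.1 / 31.3 / 12.4 / 5.4 / 4.7 percent (alternate, adjacent-1,
adjacent-2, 3:1, 4:0-or-other), multivariable odds ratios 1.293 (female
sex), 1.208 (acrocentric involvement) and 0.806 (TAR1) applied identically
to every non-alternate contrast — under which the pooled alternate-vs-rest
margin is exactly a random-intercept binary logit with those coefficients
— 2,253 carriers averaging 4.8 diagnosed blastocysts. An alternative
"per_contrast" effect set instead applies the published contrast-specific
estimates (TAR1 on adjacent-1; TS1 and sex on adjacent-2; sex and
acrocentric involvement on 3:1).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .classifier import EmbryoCNVProfile, CNVCall, MIN_SEGMENT_BP
from .karyotype import Breakpoint, ReciprocalTranslocation, compute_metrics
from .reference import ACROCENTRIC, ChromosomeTable, load_chromosome_table
from .segregation import signature_table

#: Non-alternate outcome categories of the generating multinomial logit.
CONTRASTS = ("adjacent-1", "adjacent-2", "3:1", "4:0/other")

# published marginal frequencies (percent of diagnosed blastocysts)
_BASELINE_FREQS = {
    "alternate": 46.1,
    "adjacent-1": 31.3,
    "adjacent-2": 12.4,
    "3:1": 5.4,
    "4:0/other": 4.7,
}

# multivariable ORs, pooled unbalanced-vs-alternate model
_BINARY_ORS = {"sex_female": 1.293, "acr_involved": 1.208, "tar1": 0.806}

# contrast-specific multivariable ORs (ts1 per Mb)
_PER_CONTRAST_ORS: dict[str, dict[str, float]] = {
    "adjacent-1": {"tar1": 0.316},
    "adjacent-2": {"ts1": 1.014, "sex_female": 1.66},
    "3:1": {"sex_female": 2.643, "acr_involved": 1.387},
    "4:0/other": {},
}


class ConfigError(ValueError):
    """Simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Full specification of a synthetic cohort; a pure function of this
    object (seed included) determines the output."""

    n_carriers: int = 2253
    p_female: float = 0.544  # 1,225 of 2,253 carriers
    embryos_per_carrier: float = 4.8  # Poisson mean, truncated at >= 1
    seed: int = 0

    # karyotype sampler
    min_segment_bp: int = 5_000_000
    pair_weights: dict[str, float] | None = None  # "a-b" -> weight

    # mode model: baseline logits (vs alternate) and per-contrast
    # coefficients on centred covariates
    baseline_logits: dict[str, float] = field(
        default_factory=lambda: {
            k: float(np.log(_BASELINE_FREQS[k] / _BASELINE_FREQS["alternate"]))
            for k in CONTRASTS
        }
    )
    coefficients: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            k: {c: float(np.log(v)) for c, v in _BINARY_ORS.items()}
            for k in CONTRASTS
        }
    )
    covariate_centers: dict[str, float] = field(
        default_factory=lambda: {
            "sex_female": 0.544,
            "acr_involved": 95 / 231,  # uniform-pair acrocentric rate
            "tar1": 0.5,
            "ts1": 60.0,  # Mb
        }
    )
    random_intercept_sd: float = 0.5

    # profile emission
    cnv_noise_sd_bp: float = 1_000_000.0
    incidental_aneuploidy_rate: float = 0.25  # 1,289 of 5,005 alternates
    nd_rate: float = 1.0 - 4 / 510  # P(ND | "4:0/other"); rest emit true 4:0

    # carrier age (years); not an outcome driver by default
    age_mean: float = 30.0
    age_sd: float = 4.0

    def validate(self) -> None:
        probs = {
            "p_female": self.p_female,
            "incidental_aneuploidy_rate": self.incidental_aneuploidy_rate,
            "nd_rate": self.nd_rate,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name, v in (
            ("random_intercept_sd", self.random_intercept_sd),
            ("cnv_noise_sd_bp", self.cnv_noise_sd_bp),
        ):
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v}")
        if self.n_carriers < 1:
            raise ConfigError("n_carriers must be >= 1")
        if self.embryos_per_carrier <= 0:
            raise ConfigError("embryos_per_carrier must be > 0")
        if set(self.baseline_logits) != set(CONTRASTS):
            raise ConfigError(f"baseline_logits must have keys {CONTRASTS}")
        if set(self.coefficients) != set(CONTRASTS):
            raise ConfigError(f"coefficients must have keys {CONTRASTS}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        return cls.from_dict(json.loads(text))


def default_config_from_paper(
    *, effects: str = "binary", seed: int = 0, n_carriers: int = 2253
) -> SimulationConfig:
    """Configuration calibrated to the published cohort.

    ``effects="binary"`` (default) applies the pooled multivariable ORs
    (female 1.293, Acr-ch 1.208, TAR1 0.806) to every non-alternate
    contrast; ``effects="per_contrast"`` applies the contrast-specific
    estimates instead. Baseline logits reproduce the published marginal
    mode frequencies at covariate means and zero random effect.
    """
    cfg = SimulationConfig(seed=seed, n_carriers=n_carriers)
    if effects == "per_contrast":
        cfg.coefficients = {
            k: {c: float(np.log(v)) for c, v in _PER_CONTRAST_ORS[k].items()}
            for k in CONTRASTS
        }
    elif effects == "null":
        cfg.coefficients = {k: {} for k in CONTRASTS}
    elif effects != "binary":
        raise ConfigError(f"unknown effects preset {effects!r}")
    cfg.validate()
    return cfg


@dataclass
class SimulatedCohort:
    """Carrier table, embryo truth table, CNV profiles and provenance."""

    carriers: pd.DataFrame
    truth: pd.DataFrame
    profiles: list[EmbryoCNVProfile]
    translocations: dict[str, ReciprocalTranslocation]
    config: SimulationConfig

    def calls_frame(self) -> pd.DataFrame:
        """All CNV calls as a flat BED-like frame."""
        rows = [
            {
                "embryo_id": p.embryo_id,
                "carrier_id": p.carrier_id,
                "chrom": c.chromosome,
                "start": c.start_bp,
                "end": c.end_bp,
                "copy_number": c.copy_number,
            }
            for p in self.profiles
            for c in p.calls
        ]
        cols = ["embryo_id", "carrier_id", "chrom", "start", "end", "copy_number"]
        return pd.DataFrame(rows, columns=cols)


# mode -> non-recombinant compositions, used for uniform within-mode draws
def _mode_compositions() -> dict[str, list[tuple[tuple[int, ...], object]]]:
    from .segregation import enumerate_gamete_classes, embryo_signature

    out: dict[str, list] = {}
    for g in enumerate_gamete_classes(include_recombinants=False):
        out.setdefault(g.mode, []).append((g, embryo_signature(g)))
    return out


def _sample_breakpoint(
    chrom: str, table: ChromosomeTable, rng: np.random.Generator, min_seg: int
) -> Breakpoint:
    rec = table[chrom]
    arms = []
    # translocated segment (breakpoint -> telomere) at least min_seg; keep
    # 1 Mb clear of the centromere; acrocentric p arms excluded
    lo_p, hi_p = min_seg, rec.cen_start_bp - 1_000_000
    if hi_p > lo_p and not rec.is_acrocentric:
        arms.append(("p", lo_p, hi_p))
    lo_q, hi_q = rec.cen_end_bp + 1_000_000, rec.length_bp - min_seg
    if hi_q > lo_q:
        arms.append(("q", lo_q, hi_q))
    if not arms:
        raise ConfigError(f"chromosome {chrom}: no arm admits min segment {min_seg}")
    spans = np.array([hi - lo for _, lo, hi in arms], dtype=float)
    arm, lo, hi = arms[rng.choice(len(arms), p=spans / spans.sum())]
    return Breakpoint(chromosome=chrom, arm=arm, position_bp=int(rng.integers(lo, hi)))


def _sample_pair(
    rng: np.random.Generator, weights: dict[str, float] | None
) -> tuple[str, str]:
    autosomes = [str(i) for i in range(1, 23)]
    pairs = [
        (a, b) for i, a in enumerate(autosomes) for b in autosomes[i + 1 :]
    ]
    if weights is None:
        w = np.ones(len(pairs))
    else:
        w = np.array([weights.get(f"{a}-{b}", 0.0) for a, b in pairs])
        if w.sum() <= 0:
            raise ConfigError("pair_weights assign no mass to any autosome pair")
    return pairs[rng.choice(len(pairs), p=w / w.sum())]


def _jitter_interval(
    chrom: str, start: int, end: int,
    breakpoints: set[int],
    sd: float,
    length: int,
    rng: np.random.Generator,
) -> tuple[int, int] | None:
    """Jitter interval ends that sit on a quadrivalent breakpoint; clamp to
    the chromosome and apply the platform floor."""
    s, e = float(start), float(end)
    if sd > 0:
        if start in breakpoints:
            s += rng.normal(0.0, sd)
        if end in breakpoints:
            e += rng.normal(0.0, sd)
    s = int(np.clip(round(s), 0, length))
    e = int(np.clip(round(e), 0, length))
    if e - s < MIN_SEGMENT_BP:
        return None
    return s, e


def _corrupt_profile(
    tr: ReciprocalTranslocation,
    table: ChromosomeTable,
    rng: np.random.Generator,
) -> list[CNVCall]:
    """A spurious mid-arm segment on an involved chromosome, placed so that
    both ends are far (>= 6 Mb) from every segment boundary — robustly
    uninterpretable at the default 5 Mb matching tolerance."""
    from .segregation import segment_intervals

    seg = segment_intervals(tr, table)
    # longest quadrivalent segment hosts the spurious call
    chrom, s0, e0 = max(seg.intervals.values(), key=lambda iv: iv[2] - iv[1])
    margin = 6_000_000
    lo, hi = s0 + margin, e0 - margin
    width = max(MIN_SEGMENT_BP, min(5_000_000, (hi - lo) // 2))
    start = int(rng.integers(lo, hi - width))
    cn = int(rng.choice([1, 3]))
    return [CNVCall(chromosome=chrom, start_bp=start, end_bp=start + width, copy_number=cn)]


def simulate_cohort(
    cfg: SimulationConfig, chrom_table: ChromosomeTable | None = None
) -> SimulatedCohort:
    """Generate a cohort; deterministic given the config (seed included)."""
    cfg.validate()
    if chrom_table is None:
        chrom_table = load_chromosome_table()
    root = np.random.SeedSequence(cfg.seed)
    carrier_seeds = root.spawn(cfg.n_carriers)
    comps = _mode_compositions()
    centers = cfg.covariate_centers

    carrier_rows = []
    truth_rows = []
    profiles: list[EmbryoCNVProfile] = []
    translocations: dict[str, ReciprocalTranslocation] = {}

    uninvolved_pool = [str(i) for i in range(1, 23)]

    for ci in range(cfg.n_carriers):
        rng = np.random.default_rng(np.random.Philox(carrier_seeds[ci]))
        cid = f"C{ci:05d}"
        sex = "female" if rng.random() < cfg.p_female else "male"
        age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 20.0, 45.0))
        ca, cb = _sample_pair(rng, cfg.pair_weights)
        tr = ReciprocalTranslocation(
            carrier_id=cid,
            carrier_sex=sex,
            carrier_age=age,
            bp1=_sample_breakpoint(ca, chrom_table, rng, cfg.min_segment_bp),
            bp2=_sample_breakpoint(cb, chrom_table, rng, cfg.min_segment_bp),
        )
        translocations[cid] = tr
        metrics = compute_metrics(tr, chrom_table)
        sig_table = signature_table(tr, chrom_table)
        sig_by_dosage = {k: v for k, v in sig_table.items()}

        x = {
            "sex_female": 1.0 if sex == "female" else 0.0,
            "acr_involved": 1.0 if metrics.acr_involved else 0.0,
            "tar1": metrics.tar1,
            "ts1": metrics.ts1 / 1e6,
        }
        u = rng.normal(0.0, cfg.random_intercept_sd)
        logits = np.zeros(1 + len(CONTRASTS))
        for k, contrast in enumerate(CONTRASTS, start=1):
            eta = cfg.baseline_logits[contrast] + u
            for cov, beta in cfg.coefficients[contrast].items():
                eta += beta * (x[cov] - centers.get(cov, 0.0))
            logits[k] = eta
        pvec = np.exp(logits - logits.max())
        pvec /= pvec.sum()

        row = {
            "carrier_id": cid, "sex": sex, "age": age,
            "chrom1": tr.bp1.chromosome, "pos1": tr.bp1.position_bp,
            "chrom2": tr.bp2.chromosome, "pos2": tr.bp2.position_bp,
        }
        row.update(metrics.as_row())
        carrier_rows.append(row)

        n_embryos = 0
        while n_embryos == 0:
            n_embryos = int(rng.poisson(cfg.embryos_per_carrier))
        breakpoint_positions = {tr.bp1.position_bp, tr.bp2.position_bp}
        involved = set(tr.chromosomes)
        free_chroms = [c for c in uninvolved_pool if c not in involved]

        for ei in range(n_embryos):
            eid = f"{cid}.E{ei:02d}"
            cat = ("alternate", *CONTRASTS)[rng.choice(5, p=pvec)]
            calls: list[CNVCall] = []
            true_mode = cat
            composition = ""
            nd = False
            if cat == "4:0/other" and rng.random() < cfg.nd_rate:
                nd = True
                true_mode = "ND"
                calls.extend(_corrupt_profile(tr, chrom_table, rng))
            elif cat != "alternate":
                mode = "4:0" if cat == "4:0/other" else cat
                true_mode = mode
                pool = comps[mode]
                # 4:0 null product (no chromosomes) is a lethal double
                # monosomy; both poles are emitted as drawn
                g, sig = pool[rng.choice(len(pool))]
                composition = "+".join(g.composition)
                entry = sig_by_dosage[sig.dosage.as_tuple()]
                for chrom, s, e, cn in entry.intervals:
                    jittered = _jitter_interval(
                        chrom, s, e, breakpoint_positions,
                        cfg.cnv_noise_sd_bp, chrom_table[chrom].length_bp, rng,
                    )
                    if jittered is not None:
                        calls.append(
                            CNVCall(
                                chromosome=chrom, start_bp=jittered[0],
                                end_bp=jittered[1], copy_number=cn,
                            )
                        )
            incidental = bool(rng.random() < cfg.incidental_aneuploidy_rate)
            if incidental:
                chrom = free_chroms[rng.choice(len(free_chroms))]
                cn = int(rng.choice([1, 3]))
                calls.append(
                    CNVCall(
                        chromosome=chrom, start_bp=0,
                        end_bp=chrom_table[chrom].length_bp, copy_number=cn,
                    )
                )
            profiles.append(
                EmbryoCNVProfile(embryo_id=eid, carrier_id=cid, calls=tuple(calls))
            )
            truth_rows.append(
                {
                    "embryo_id": eid,
                    "carrier_id": cid,
                    "true_mode": true_mode,
                    "category": cat,
                    "composition": composition,
                    "incidental_aneuploidy": incidental,
                    "nd": nd,
                }
            )

    carriers = pd.DataFrame(carrier_rows)
    truth = pd.DataFrame(truth_rows)
    return SimulatedCohort(
        carriers=carriers, truth=truth, profiles=profiles,
        translocations=translocations, config=cfg,
    )
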