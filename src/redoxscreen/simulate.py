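"""Seeded generators for screen plates, count matrices and annotations.

Every generator is a pure function of its config and seed, and returns the
planted ground truth alongside the data so recovery can be scored exactly.
Noise models are deliberately minimal and standard: log-normal reporter
ratios for the luciferase screen and negative-binomial counts
(variance mu + phi*mu^2) for RNA-seq.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CONDITIONS

#: reporter effect of the assay-validation controls: knocking down the
#: pathway transcription factor (CncC) or its partner (MafS) suppresses the
#: reporter; knocking down the pathway inhibitor (Keap1) nudges it up; a GFP
#: dsRNA is inert.  Magnitudes echo the published validation Z-scores.
CONTROL_EFFECTS = {
    "CncC": ("pathway-positive", 0.55),
    "MafS": ("pathway-positive", 0.65),
    "Keap1": ("pathway-negative", 1.07),
    "GFP": ("neutral", 1.0),
}


@dataclass(frozen=True)
class ScreenSimConfig:
    """Kinome-screen simulation: 432 genes x 3 dsRNAs on 384-well plates."""

    n_genes: int = 432
    n_dsrna_per_gene: int = 3
    plate_size: int = 384
    baseline_log_mean: float = 0.0
    baseline_log_sigma: float = 0.1
    rluc_log_mean: float = math.log(5e4)
    rluc_log_sigma: float = 0.2
    inducer_effect: float = 0.2     # multiplicative Fluc suppression, in (0, 1)
    suppressor_effect: float = 2.0  # multiplicative Fluc gain, > 1
    p_inert_dsrna: float = 1 / 3    # chance a hit gene carries one inert dsRNA
    n_planted_inducers: int = 10
    n_planted_suppressors: int = 6
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.inducer_effect):
            raise ValueError("inducer_effect must be positive")
        if self.suppressor_effect <= 0:
            raise ValueError("suppressor_effect must be positive")
        if not (0 <= self.p_inert_dsrna <= 1):
            raise ValueError("p_inert_dsrna must be a probability")
        if self.n_planted_inducers + self.n_planted_suppressors > self.n_genes:
            raise ValueError("more planted hits than genes")
        if self.plate_size <= len(CONTROL_EFFECTS):
            raise ValueError("plate too small for control wells")


@dataclass(frozen=True)
class CountsSimConfig:
    """Four-condition RNA-seq simulation with planted expression patterns.

    Group A genes follow mu = m * (1, fold_pq_induction, 1, 1) across
    (Control, Paraquat, Cdk12i, Cdk12i+Paraquat): paraquat-induced, ablated
    under Cdk12 knockdown.  Group B genes follow
    mu = m * (1, 1, 1/cdk12i_fold, fold_b_induction): induced only under the
    combined treatment, with a basal Cdk12 dependence (repressed
    cdk12i_fold-fold under knockdown alone) whose direction is immaterial to
    the direction-free Cdk12i/Control significance criterion but gives every
    pairwise comparison the criteria test a real effect and keeps the
    standardized profile firmly low-low-low-high.

    Background genes draw a constant per-gene mean around ``background_mean``,
    set well above the planted baseline so that background mass dominates the
    library, as in a real transcriptome where a few dozen responsive genes
    are a negligible share of sequenced reads; this keeps CPM composition
    shifts at the realistic, small scale.
    """

    n_background: int = 400
    n_group_a: int = 30
    n_group_b: int = 30
    n_housekeeping: int = 40
    baseline_mean: float = 100.0
    background_mean: float = 500.0
    fold_pq_induction: float = 8.0   # Group A: Paraquat vs Control
    fold_b_induction: float = 4.0    # Group B: Cdk12i+Paraquat vs baseline
    cdk12i_fold: float = 4.0         # Group B: basal repression under Cdk12i
    dispersion: float = 0.1          # NB phi, variance mu + phi*mu^2
    n_replicates: int = 3
    libsize_jitter: float = 0.2      # uniform +/- fraction per sample
    background_log_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("fold_pq_induction", "fold_b_induction", "cdk12i_fold"):
            if getattr(self, name) <= 1:
                raise ValueError(f"{name} must exceed 1")
        if self.dispersion <= 0 or self.baseline_mean <= 0:
            raise ValueError("dispersion and baseline_mean must be positive")
        if not (0 <= self.libsize_jitter < 1):
            raise ValueError("libsize_jitter must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    """Planted gene roles and per-gene effect sizes."""

    roles: dict[str, set[str]] = field(default_factory=dict)
    effects: dict[str, float] = field(default_factory=dict)

    def genes(self, role: str) -> set[str]:
        return set(self.roles.get(role, set()))

    def all_genes(self) -> set[str]:
        out = set()
        for genes in self.roles.values():
            out |= genes
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "role": role, "effect": self.effects.get(g, np.nan)}
            for role, genes in sorted(self.roles.items())
            for g in sorted(genes)
        ]
        return pd.DataFrame(rows, columns=["gene_id", "role", "effect"])


def _well_ids(plate_size: int) -> list[str]:
    n_cols = 24 if plate_size == 384 else max(1, int(math.ceil(math.sqrt(plate_size))))
    n_rows = int(math.ceil(plate_size / n_cols))
    ids = [
        f"{chr(ord('A') + r)}{c + 1:02d}" for r in range(n_rows) for c in range(n_cols)
    ]
    return ids[:plate_size]


def gen_screen(
    cfg: ScreenSimConfig = ScreenSimConfig(), seed: int | None = None
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a dual-luciferase kinome screen with planted hits.

    Each plate carries one well per control knockdown (CncC, MafS, Keap1,
    GFP) plus library wells.  A well's reporter ratio is a log-normal
    baseline draw times the dsRNA effect, applied to Fluc only; Rluc is an
    independent log-normal draw.  For a fraction of hit genes one randomly
    chosen dsRNA is inert, reproducing the partially-consistent reagents
    that motivate the 2-of-3 consensus rule.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genes = [f"g{i + 1:03d}" for i in range(cfg.n_genes)]
    order = rng.permutation(cfg.n_genes)
    inducers = {genes[i] for i in order[: cfg.n_planted_inducers]}
    suppressors = {
        genes[i]
        for i in order[cfg.n_planted_inducers: cfg.n_planted_inducers + cfg.n_planted_suppressors]
    }

    effects: dict[str, float] = {}
    dsrna_effect: dict[str, float] = {}
    for g in genes:
        eff = 1.0
        if g in inducers:
            eff = cfg.inducer_effect
        elif g in suppressors:
            eff = cfg.suppressor_effect
        effects[g] = eff
        inert = -1
        if eff != 1.0 and rng.random() < cfg.p_inert_dsrna:
            inert = int(rng.integers(cfg.n_dsrna_per_gene))
        for j in range(cfg.n_dsrna_per_gene):
            dsrna_effect[f"{g}_ds{j + 1}"] = 1.0 if j == inert else eff

    controls = list(CONTROL_EFFECTS)
    wells_per_plate = cfg.plate_size - len(controls)
    library = list(dsrna_effect)
    n_plates = int(math.ceil(len(library) / wells_per_plate))
    well_ids = _well_ids(cfg.plate_size)

    rows = []
    pos = 0
    for p in range(n_plates):
        plate_id = f"P{p + 1:02d}"
        plate_wells = iter(well_ids)
        for cg in controls:
            role, eff = CONTROL_EFFECTS[cg]
            rows.append((plate_id, next(plate_wells), cg, f"{cg}_ds_{plate_id}", eff, role))
        for ds in library[pos: pos + wells_per_plate]:
            gene = ds.rsplit("_ds", 1)[0]
            rows.append((plate_id, next(plate_wells), gene, ds, dsrna_effect[ds], "none"))
        pos += wells_per_plate

    n = len(rows)
    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sigma, n)
    rluc = rng.lognormal(cfg.rluc_log_mean, cfg.rluc_log_sigma, n)
    table = pd.DataFrame(rows, columns=["plate_id", "well_id", "gene_id", "dsrna_id",
                                        "effect", "control_role"])
    table["rluc"] = rluc
    table["fluc"] = baseline * table.pop("effect") * rluc
    table = table[["plate_id", "well_id", "gene_id", "dsrna_id", "fluc", "rluc", "control_role"]]

    truth = SyntheticTruth(
        roles={
            "inducer": inducers,
            "suppressor": suppressors,
            "control": set(controls),
            "background": set(genes) - inducers - suppressors,
        },
        effects={**effects, **{g: CONTROL_EFFECTS[g][1] for g in controls}},
    )
    return table, truth


def gen_counts(
    cfg: CountsSimConfig = CountsSimConfig(), seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate the 4-condition x n-replicate count matrix.

    Returns ``(counts, design, truth)``; counts rows are shuffled so gene
    order carries no information about the planted roles.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    m = cfg.baseline_mean
    profiles: dict[str, np.ndarray] = {}
    roles: dict[str, set[str]] = {
        "group_a": set(), "group_b": set(), "housekeeping": set(), "background": set(),
    }
    effects: dict[str, float] = {}

    for i in range(cfg.n_group_a):
        g = f"ga{i + 1:04d}"
        profiles[g] = m * np.array([1.0, cfg.fold_pq_induction, 1.0, 1.0])
        roles["group_a"].add(g)
        effects[g] = cfg.fold_pq_induction
    for i in range(cfg.n_group_b):
        g = f"gb{i + 1:04d}"
        profiles[g] = m * np.array([1.0, 1.0, 1.0 / cfg.cdk12i_fold, cfg.fold_b_induction])
        roles["group_b"].add(g)
        effects[g] = cfg.fold_b_induction
    for i in range(cfg.n_housekeeping):
        g = f"hk{i + 1:04d}"
        profiles[g] = m * np.ones(4)
        roles["housekeeping"].add(g)
        effects[g] = 1.0
    bg_means = rng.lognormal(math.log(cfg.background_mean), cfg.background_log_sigma,
                             cfg.n_background)
    for i in range(cfg.n_background):
        g = f"bg{i + 1:04d}"
        profiles[g] = bg_means[i] * np.ones(4)
        roles["background"].add(g)
        effects[g] = 1.0

    samples = [f"{cond}_{r + 1}" for cond in CONDITIONS for r in range(cfg.n_replicates)]
    design = pd.DataFrame(
        {
            "condition": [s.rsplit("_", 1)[0] for s in samples],
            "replicate": [int(s.rsplit("_", 1)[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    libfac = rng.uniform(1 - cfg.libsize_jitter, 1 + cfg.libsize_jitter, len(samples))

    genes = list(profiles)
    mu = np.stack([profiles[g] for g in genes])            # gene x condition
    cond_idx = [CONDITIONS.index(c) for c in design["condition"]]
    mu_sample = mu[:, cond_idx] * libfac                   # gene x sample
    r = 1.0 / cfg.dispersion
    counts = rng.negative_binomial(r, r / (r + mu_sample))
    out = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)
    out = out.iloc[rng.permutation(len(out))]

    return out, design, SyntheticTruth(roles=roles, effects=effects)


def gen_annotation(
    truth: SyntheticTruth,
    n_noise_terms: int = 20,
    enriched_fraction: float = 0.8,
    background_per_term: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Build an annotation table with one enriched term per planted role.

    Each non-empty role gets a term annotating ``enriched_fraction`` of its
    genes plus ``background_per_term`` genes drawn from outside the role;
    ``n_noise_terms`` additional terms annotate random gene sets.
    """
    if not (0 < enriched_fraction <= 1):
        raise ValueError("enriched_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    universe = sorted(truth.all_genes())
    rows = []
    for role in sorted(truth.roles):
        members = sorted(truth.roles[role])
        if not members:
            continue
        n_in = max(1, round(enriched_fraction * len(members)))
        chosen = list(rng.choice(members, size=n_in, replace=False))
        outside = sorted(set(universe) - set(members))
        if background_per_term and outside:
            chosen += list(
                rng.choice(outside, size=min(background_per_term, len(outside)), replace=False)
            )
        term_id = f"ROLE:{role}"
        for g in sorted(chosen):
            rows.append({"term_id": term_id, "term_name": f"{role} signature", "gene_id": g})
    for t in range(n_noise_terms):
        size = int(rng.integers(5, min(31, len(universe) + 1)))
        for g in sorted(rng.choice(universe, size=size, replace=False)):
            rows.append(
                {"term_id": f"NOISE:{t + 1:03d}", "term_name": f"random set {t + 1}", "gene_id": g}
            )
    return pd.DataFrame(rows, columns=["term_id", "term_name", "gene_id"])
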