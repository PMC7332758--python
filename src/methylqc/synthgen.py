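"""Synthetic two-tissue methylation study generator.

Emulates the statistical structure the downstream pipeline assumes: paired
blood/CSF subjects with longitudinal CSF draws at target days 1/4/7/10/13,
plate/chip/row/column batch effects on the M scale, per-sample cell-type
mixtures drawn from tissue-specific reference methylomes, latent sample
factors (cell-type-heterogeneity-like variation for SVA to find), planted
failing samples and multimodal probes, fixed-methylation control samples
(0/30/70/100%) and technical replicates per plate, and region-dependent
cross-tissue coupling so that blood-CSF within-CpG correlation has a known
target per genomic-region category.

Everything is driven by a :class:`SimConfig` and a single integer seed; with
the seed fixed the (dataset, truth) pair is reproducible bit for bit.  The
:class:`TruthRecord` carries the planted ground truth (cell fractions, batch
offsets, failing samples, latent factors, coupling targets) for recovery
tests.

The CSF cell-type panel (lymphocyte, monocyte, neutrophil, rbc_remnant) is a
modeling choice: no methylation reference exists for post-hemorrhage CSF, so
the generator simply needs *some* mixture structure there; it makes no claim
of biological fidelity.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    ANNOTATION_COLUMNS,
    CONTROL_BETAS,
    MethylationDataset,
    REGIONS,
    ORIENTATIONS,
    SAMPLE_SHEET_COLUMNS,
    beta_from_m,
    m_from_beta,
)

BLOOD_CELL_TYPES = ("CD4T", "CD8T", "NK", "monocyte", "B_cell", "granulocyte")
CSF_CELL_TYPES = ("lymphocyte", "monocyte", "neutrophil", "rbc_remnant")

ROWS_PER_CHIP = 6
COLS_PER_CHIP = 2
CHIPS_PER_PLATE = 8
POSITIONS_PER_CHIP = ROWS_PER_CHIP * COLS_PER_CHIP
POSITIONS_PER_PLATE = CHIPS_PER_PLATE * POSITIONS_PER_CHIP  # 96

FAILURE_MODES = (
    "low_bisulfite",
    "high_detection_failure",
    "intensity_outlier",
    "beta_outlier",
)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SimConfig:
    """Generator configuration; defaults give ~2,000 probes x ~120 samples."""

    n_probes: int = 2000
    n_subjects: int = 24                 # subjects with longitudinal CSF
    n_blood_subjects: int = 20           # subset also providing day-1 blood
    target_days: tuple = (1, 4, 7, 10, 13)
    day_availability: float = 0.85       # P(a usable draw exists near a target day)
    day_jitter_prob: float = 0.2         # P(draw lands +/-1 day off target | available)

    # mixture model
    blood_dirichlet: tuple = (7.5, 5.0, 2.5, 5.0, 2.5, 27.5)   # mean ~ typical blood
    csf_dirichlet: tuple = (12.0, 9.0, 6.0, 3.0)
    n_discriminating: int = 300          # probes separating cell types in the references

    # M-scale variation
    batch_sd_plate: float = 0.25
    batch_sd_chip: float = 0.20
    batch_sd_row: float = 0.10
    batch_sd_column: float = 0.05
    n_latent_factors: int = 3
    factor_loading_sd: float = 0.35      # per-probe loading scale of latent factors
    bio_sd: float = 0.8                  # subject-level biological deviation (M scale)
    noise_sigma: float = 0.1             # multiplicative log-normal channel noise

    # cross-tissue coupling targets by region
    region_correlation: dict = dataclasses.field(
        default_factory=lambda: {"island": 0.60, "shore": 0.45, "shelf": 0.25, "open_sea": 0.10}
    )

    # planted artifacts
    failures_csf: dict = dataclasses.field(
        default_factory=lambda: {
            "low_bisulfite": 2,
            "high_detection_failure": 2,
            "intensity_outlier": 1,
            "beta_outlier": 1,
        }
    )
    failures_blood: dict = dataclasses.field(
        default_factory=lambda: {"beta_outlier": 1}
    )
    n_multimodal_probes: int = 30
    n_bcell_outliers: int = 1            # CLL-like blood samples (B-cell excess)

    # intensity model
    mean_total_intensity: float = 5000.0
    background_mean: float = 180.0       # per-channel negative-control level
    background_sd: float = 45.0
    bisulfite_mean: float = 4000.0
    bisulfite_sample_sd: float = 0.05    # log-scale between-sample spread
    dye_bias_sd: float = 0.15            # log-scale per-sample channel imbalance
    n_negative_controls: int = 20
    n_bisulfite_controls: int = 10
    n_norm_controls: int = 10

    # annotation composition
    frac_sex_chromosome: float = 0.04
    frac_snp_overlap: float = 0.05
    frac_cross_reactive: float = 0.04

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self, n_samples_csf: int, n_samples_blood: int) -> None:
        for name, failures, n in (
            ("csf", self.failures_csf, n_samples_csf),
            ("blood", self.failures_blood, n_samples_blood),
        ):
            bad = set(failures) - set(FAILURE_MODES)
            if bad:
                raise ValueError(f"unknown failure modes for {name}: {sorted(bad)}")
            if sum(failures.values()) > n:
                raise ValueError(
                    f"more planted failures ({sum(failures.values())}) than {name} samples ({n})"
                )
        if self.n_multimodal_probes > self.n_probes:
            raise ValueError("more multimodal probes than probes")


# ---------------------------------------------------------------------------
# truth record
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TruthRecord:
    """Planted ground truth accompanying a simulated dataset."""

    cell_fractions: pd.DataFrame          # sample x cell_type (per tissue panel)
    batch_effects: dict                   # level -> {key: M-scale offset}
    failing_samples: list                 # [(sample_id, mode), ...]
    multimodal_probes: list
    region_correlation: dict
    sv_factors: pd.DataFrame              # sample x factor loadings
    #: probe x cell-type reference betas per tissue (generator ground truth)
    references: dict | None = None
    #: blood samples planted with a CLL-like B-cell excess
    composition_outliers: list = dataclasses.field(default_factory=list)

    def __post_init__(self):
        sums = self.cell_fractions.sum(axis=1, skipna=True).to_numpy()
        if np.nanmax(np.abs(sums - 1.0)) > 1e-9:
            raise ValueError("cell fraction rows must sum to 1")

    def failing_ids(self, mode: str | None = None) -> list:
        return [s for s, m in self.failing_samples if mode is None or m == mode]

    def to_json(self, path) -> None:
        payload = {
            "cell_fractions": self.cell_fractions.to_dict(orient="index"),
            "batch_effects": self.batch_effects,
            "failing_samples": [list(x) for x in self.failing_samples],
            "multimodal_probes": list(self.multimodal_probes),
            "region_correlation": self.region_correlation,
            "sv_factors": self.sv_factors.to_dict(orient="index"),
            "references": {t: r.to_dict(orient="index")
                           for t, r in (self.references or {}).items()},
            "composition_outliers": list(self.composition_outliers),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            cell_fractions=pd.DataFrame.from_dict(payload["cell_fractions"], orient="index"),
            batch_effects=payload["batch_effects"],
            failing_samples=[tuple(x) for x in payload["failing_samples"]],
            multimodal_probes=payload["multimodal_probes"],
            region_correlation=payload["region_correlation"],
            sv_factors=pd.DataFrame.from_dict(payload["sv_factors"], orient="index"),
            references={t: pd.DataFrame.from_dict(r, orient="index")
                        for t, r in payload.get("references", {}).items()} or None,
            composition_outliers=payload.get("composition_outliers", []),
        )


# ---------------------------------------------------------------------------
# reference methylomes
# ---------------------------------------------------------------------------

def simulate_reference_methylome(
    n_probes: int,
    cell_types: Sequence[str] = BLOOD_CELL_TYPES,
    n_discriminating: int = 300,
    seed: int = 0,
    base_beta: np.ndarray | None = None,
) -> pd.DataFrame:
    """Probe x cell-type beta reference with ``n_discriminating`` probes whose
    beta is near 0 in some cell types and near 1 in others; the remaining
    probes are shared across types.

    ``base_beta`` fixes the shared (non-discriminating) profile so that two
    tissues can be built on a common methylome architecture.
    """
    if n_discriminating > n_probes:
        raise ValueError("n_discriminating exceeds n_probes")
    rng = np.random.default_rng(seed)
    k = len(cell_types)
    if base_beta is None:
        # bimodal-ish genome-wide profile typical of methylation arrays
        low = rng.beta(1.5, 12, size=n_probes)
        high = rng.beta(12, 1.5, size=n_probes)
        base_beta = np.where(rng.random(n_probes) < 0.45, low, high)
    ref = np.tile(base_beta[:, None], (1, k))
    idx = rng.choice(n_probes, size=n_discriminating, replace=False)
    for p in idx:
        # split cell types into a hypo and a hyper group
        n_low = rng.integers(1, k)
        order = rng.permutation(k)
        ref[p, order[:n_low]] = rng.uniform(0.02, 0.15, size=n_low)
        ref[p, order[n_low:]] = rng.uniform(0.85, 0.98, size=k - n_low)
    probes = [f"cg{i:07d}" for i in range(n_probes)]
    return pd.DataFrame(ref, index=probes, columns=list(cell_types))


# ---------------------------------------------------------------------------
# plate layout
# ---------------------------------------------------------------------------

def _checkerboard_fill(chip_samples: pd.DataFrame, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Assign (row, column) positions on a 6x2 chip alternating trait by
    parity where counts permit; greedy max-alternation otherwise.

    Returns positions aligned with chip_samples rows.
    """
    positions = [(r, c) for r in range(1, ROWS_PER_CHIP + 1) for c in range(1, COLS_PER_CHIP + 1)]
    par0 = [p for p in positions if (p[0] + p[1]) % 2 == 0]
    par1 = [p for p in positions if (p[0] + p[1]) % 2 == 1]
    cases = list(chip_samples.index[chip_samples["trait"] == 1])
    others = list(chip_samples.index[chip_samples["trait"] != 1])
    assign: dict = {}
    for ids, pool, spill in ((cases, par0, par1), (others, par1, par0)):
        for sid in ids:
            if pool:
                assign[sid] = pool.pop(0)
            else:
                assign[sid] = spill.pop(0)
    return [assign[i] for i in chip_samples.index]


def generate_plate_layout(
    subjects: pd.DataFrame,
    seed: int = 0,
    n_plates: int | None = None,
) -> pd.DataFrame:
    """Build a sample sheet with plate/chip/row/column assignments.

    ``subjects`` has one row per biological draw: subject_id, tissue,
    collection_day, trait, age, sex.  Constraints honoured:

    * all longitudinal draws of a subject share one chip (max 12 per subject);
    * within a chip, trait cases/controls alternate in a checkerboard on the
      6x2 grid where counts permit;
    * each plate reserves 8 wells on its last chip for four fixed-methylation
      control samples (0/30/70/100%; two at fixed wells, two seeded-random)
      and four technical replicates.  For CSF plates one designated sample
      recurs as a replicate on every plate.
    """
    rng = np.random.default_rng(seed)
    rows = []
    sample_counter = {}

    def new_id(prefix):
        sample_counter[prefix] = sample_counter.get(prefix, 0) + 1
        return f"{prefix}{sample_counter[prefix]:04d}"

    for tissue in sorted(subjects["tissue"].unique()):
        tsub = subjects[subjects["tissue"] == tissue]
        groups = [grp for _, grp in tsub.groupby("subject_id")]
        for grp in groups:
            if len(grp) > POSITIONS_PER_CHIP:
                raise ValueError(
                    f"subject {grp['subject_id'].iloc[0]} has {len(grp)} longitudinal "
                    f"samples; cannot fit one chip ({POSITIONS_PER_CHIP})"
                )
        # first-fit-decreasing packing of subjects into biological chips
        groups.sort(key=len, reverse=True)
        bio_chips_per_plate = CHIPS_PER_PLATE - 1   # last chip holds controls+replicates
        chips: list[list[pd.DataFrame]] = []
        for grp in groups:
            placed = False
            for chip in chips:
                if sum(len(g) for g in chip) + len(grp) <= POSITIONS_PER_CHIP:
                    chip.append(grp)
                    placed = True
                    break
            if not placed:
                chips.append([grp])
        needed_plates = int(np.ceil(len(chips) / bio_chips_per_plate))
        if n_plates is not None and tissue == "csf":
            needed_plates = max(needed_plates, n_plates)
        prefix = "BL" if tissue == "blood" else "CS"
        recurring_rep_source = None
        for plate_i in range(needed_plates):
            plate = f"{prefix}_P{plate_i + 1:02d}"
            plate_chips = chips[plate_i * bio_chips_per_plate:(plate_i + 1) * bio_chips_per_plate]
            plate_bio_rows = []
            for chip_j, chip_groups in enumerate(plate_chips):
                chip_id = f"{plate}_C{chip_j + 1}"
                chip_df = pd.concat(chip_groups).reset_index(drop=True)
                pos = _checkerboard_fill(chip_df, rng)
                for (r, c), (_, s) in zip(pos, chip_df.iterrows()):
                    plate_bio_rows.append(dict(
                        sample_id=new_id(prefix),
                        subject_id=s["subject_id"],
                        tissue=tissue,
                        collection_day=int(s["collection_day"]),
                        plate=plate,
                        chip=chip_id,
                        row=r,
                        column=c,
                        replicate_group=None,
                        trait=s["trait"],
                        age=float(s["age"]),
                        sex=s["sex"],
                        is_control_sample=False,
                        control_beta=np.nan,
                    ))
            rows.extend(plate_bio_rows)
            # reserved chip: 4 controls + 4 technical replicates
            res_chip = f"{plate}_C{CHIPS_PER_PLATE}"
            res_positions = [(r, c) for r in range(1, ROWS_PER_CHIP + 1)
                             for c in range(1, COLS_PER_CHIP + 1)]
            fixed_pos = [(1, 1), (2, 1)]            # identical across plates
            rand_pool = [p for p in res_positions if p not in fixed_pos]
            rand_idx = rng.choice(len(rand_pool), size=6, replace=False)
            rand_pos = [rand_pool[i] for i in rand_idx]
            ctrl_pos = fixed_pos + rand_pos[:2]
            rep_pos = rand_pos[2:6]
            for beta, (r, c) in zip(CONTROL_BETAS, ctrl_pos):
                rows.append(dict(
                    sample_id=new_id(prefix),
                    subject_id=f"CTRL_{int(round(beta * 100))}",
                    tissue=tissue,
                    collection_day=0,
                    plate=plate, chip=res_chip, row=r, column=c,
                    replicate_group=None,
                    trait=np.nan, age=np.nan, sex="F",
                    is_control_sample=True, control_beta=beta,
                ))
            if not plate_bio_rows:
                continue
            # replicates: re-assays of samples on this plate; for CSF the
            # first replicate slot is one designated sample on every plate
            sources = []
            if tissue == "csf":
                if recurring_rep_source is None:
                    recurring_rep_source = plate_bio_rows[
                        int(rng.integers(len(plate_bio_rows)))]
                sources.append(recurring_rep_source)
                n_random = 3
            else:
                n_random = 4
            pick = rng.choice(len(plate_bio_rows), size=min(n_random, len(plate_bio_rows)),
                              replace=False)
            sources.extend(plate_bio_rows[i] for i in pick)
            for src, (r, c) in zip(sources, rep_pos):
                group = f"rep_{src['sample_id']}"
                src["replicate_group"] = group
                rows.append(dict(
                    sample_id=new_id(prefix),
                    subject_id=src["subject_id"],
                    tissue=tissue,
                    collection_day=src["collection_day"],
                    plate=plate, chip=res_chip, row=r, column=c,
                    replicate_group=group,
                    trait=src["trait"], age=src["age"], sex=src["sex"],
                    is_control_sample=False, control_beta=np.nan,
                ))
    sheet = pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS)
    return sheet


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(n_probes: int, cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    probes = [f"cg{i:07d}" for i in range(n_probes)]
    region = rng.choice(REGIONS, size=n_probes)          # ~equal strata
    orientation = rng.choice(ORIENTATIONS, size=n_probes)
    design = rng.choice(["I-green", "I-red", "II"], size=n_probes, p=[0.15, 0.15, 0.70])
    chrom = np.where(
        rng.random(n_probes) < cfg.frac_sex_chromosome,
        rng.choice(["X", "Y"], size=n_probes, p=[0.8, 0.2]),
        rng.choice([f"chr{i}" for i in range(1, 23)], size=n_probes),
    )
    snp = rng.random(n_probes) < cfg.frac_snp_overlap
    xr = rng.random(n_probes) < cfg.frac_cross_reactive
    ann = pd.DataFrame({
        "probe_id": probes,
        "design_type": design,
        "chromosome": chrom,
        "region": region,
        "orientation": orientation,
        "snp_overlap": snp,
        "cross_reactive": xr,
    }, index=probes)
    return ann


# ---------------------------------------------------------------------------
# the full dataset
# ---------------------------------------------------------------------------

def _draw_subjects(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Subject table and the biological draws (tissue, day) they provide."""
    rows = []
    for i in range(cfg.n_subjects):
        sid = f"subj{i + 1:03d}"
        trait = int(rng.random() < 0.45)
        age = float(np.round(rng.normal(52.5, 11.0), 1))
        sex = "F" if rng.random() < 0.68 else "M"
        for day in cfg.target_days:
            if rng.random() > cfg.day_availability:
                continue
            actual = day
            if rng.random() < cfg.day_jitter_prob:
                actual = day + int(rng.choice([-1, 1]))
            actual = max(actual, 1)
            rows.append(dict(subject_id=sid, tissue="csf", collection_day=actual,
                             trait=trait, age=age, sex=sex))
        if i < cfg.n_blood_subjects:
            rows.append(dict(subject_id=sid, tissue="blood", collection_day=1,
                             trait=trait, age=age, sex=sex))
    return pd.DataFrame(rows)


def simulate_dataset(config: SimConfig | None = None, seed: int = 0):
    """Generate a (MethylationDataset, TruthRecord) pair.

    The generative model, per biological sample s and probe p:

    ``M[p,s] = logit2(R_tissue[p,:] @ w[s,:]) + sum_k L[p,k] F[k,s]
               + batch(plate)+batch(chip)+batch(row)+batch(col)
               + bio_sd * (sqrt(rho_p) u[p,subj] + sqrt(1-rho_p) e[p,s])``

    where w are Dirichlet cell fractions, L/F latent rank-1 factors,
    rho_p the region-specific cross-tissue coupling, u a subject-probe
    deviation shared between the subject's blood and CSF samples, and e an
    independent deviation.  Betas are converted to meth/unmeth channels with
    multiplicative log-normal noise, additive background, and per-sample
    dye bias; control probes and planted failures are layered on top.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)

    # -- references on a shared methylome backbone -------------------------
    base_rng = np.random.default_rng(rng.integers(2**31))
    low = base_rng.beta(1.5, 12, size=cfg.n_probes)
    high = base_rng.beta(12, 1.5, size=cfg.n_probes)
    mid = base_rng.uniform(0.2, 0.8, size=cfg.n_probes)
    u = base_rng.random(cfg.n_probes)
    base_beta = np.where(u < 0.40, low, np.where(u < 0.80, high, mid))
    ref_blood = simulate_reference_methylome(
        cfg.n_probes, BLOOD_CELL_TYPES, cfg.n_discriminating,
        seed=int(rng.integers(2**31)), base_beta=base_beta)
    ref_csf = simulate_reference_methylome(
        cfg.n_probes, CSF_CELL_TYPES, cfg.n_discriminating,
        seed=int(rng.integers(2**31)), base_beta=base_beta)
    probes = list(ref_blood.index)

    ann = simulate_annotation(cfg.n_probes, cfg, rng)
    # multimodal probes: clean autosomal probes so they survive earlier filters
    clean = ann[~ann.snp_overlap & ~ann.cross_reactive
                & ~ann.chromosome.isin(["X", "Y"])].index.to_numpy()
    multimodal = sorted(rng.choice(clean, size=cfg.n_multimodal_probes, replace=False))
    mm_set = set(multimodal)

    # -- design ------------------------------------------------------------
    subjects = _draw_subjects(cfg, rng)
    sheet = generate_plate_layout(subjects, seed=int(rng.integers(2**31)))
    cfg.validate(
        n_samples_csf=int((sheet.tissue == "csf").sum()),
        n_samples_blood=int((sheet.tissue == "blood").sum()),
    )
    n_samples = len(sheet)
    sample_ids = list(sheet["sample_id"])

    # -- batch effects -----------------------------------------------------
    def _bounded(sd):
        # bounded batch draw (|.| < 2 sd): array artifacts are not heavy-tailed
        return float(sd * 2.0 * np.tanh(rng.normal(0, 1.0) / 2.0))

    batch = {"plate": {}, "chip": {}, "row": {}, "column": {}}
    for p in sheet["plate"].unique():
        batch["plate"][p] = _bounded(cfg.batch_sd_plate)
    for c in sheet["chip"].unique():
        batch["chip"][c] = _bounded(cfg.batch_sd_chip)
    for r in range(1, ROWS_PER_CHIP + 1):
        batch["row"][str(r)] = _bounded(cfg.batch_sd_row)
    for c in range(1, COLS_PER_CHIP + 1):
        batch["column"][str(c)] = _bounded(cfg.batch_sd_column)

    # -- latent factors ----------------------------------------------------
    k = cfg.n_latent_factors
    # deviations passed through a smooth bounded transform (2*tanh(z/2),
    # |.| < 2): methylation noise is light-tailed, and unbounded Gaussian
    # M-scale tails would fabricate satellite beta modes
    squash = lambda z: 2.0 * np.tanh(z / 2.0)
    loadings = cfg.factor_loading_sd * squash(
        rng.normal(0, 1.0, size=(cfg.n_probes, k)))
    factor_scores = squash(rng.normal(0, 1.0, size=(n_samples, k)))
    sv_factors = pd.DataFrame(factor_scores, index=sample_ids,
                              columns=[f"factor{j + 1}" for j in range(k)])

    # -- cell fractions (per biological identity, shared by replicates) ----
    frac_by_key: dict = {}
    cf_rows = {}
    all_cts = list(BLOOD_CELL_TYPES) + [c for c in CSF_CELL_TYPES if c not in BLOOD_CELL_TYPES]
    for _, s in sheet.iterrows():
        key = (s.subject_id, s.tissue, s.collection_day)
        if s.is_control_sample:
            continue
        if key not in frac_by_key:
            alpha = cfg.blood_dirichlet if s.tissue == "blood" else cfg.csf_dirichlet
            frac_by_key[key] = rng.dirichlet(alpha)
        cts = BLOOD_CELL_TYPES if s.tissue == "blood" else CSF_CELL_TYPES
        cf_rows[s.sample_id] = dict(zip(cts, frac_by_key[key]))
    # CLL-like planted outliers: override a blood identity with B-cell excess
    composition_outliers = []
    blood_keys = sorted(k for k in frac_by_key if k[1] == "blood")
    if cfg.n_bcell_outliers and blood_keys:
        picks = rng.choice(len(blood_keys), size=min(cfg.n_bcell_outliers, len(blood_keys)),
                           replace=False)
        b_idx = list(BLOOD_CELL_TYPES).index("B_cell")
        for i in picks:
            key = blood_keys[int(i)]
            w = frac_by_key[key].copy()
            w *= 0.25 / (w.sum() - w[b_idx])
            w[b_idx] = 0.75
            frac_by_key[key] = w / w.sum()
        outlier_keys = {blood_keys[int(i)] for i in picks}
        for sid, s_row in zip(sheet["sample_id"],
                              sheet[["subject_id", "tissue", "collection_day"]].itertuples(index=False)):
            if (s_row.subject_id, s_row.tissue, s_row.collection_day) in outlier_keys:
                composition_outliers.append(sid)
        for sid in composition_outliers:
            if sid in cf_rows:
                cf_rows[sid] = dict(zip(BLOOD_CELL_TYPES,
                                        frac_by_key[(sheet.set_index("sample_id").loc[sid, "subject_id"],
                                                     "blood",
                                                     int(sheet.set_index("sample_id").loc[sid, "collection_day"]))]))
    cell_fractions = pd.DataFrame.from_dict(cf_rows, orient="index").reindex(columns=all_cts)
    # rows sum to 1 over the tissue's own panel; absent panel entries are NaN

    # -- subject-level coupled deviations ----------------------------------
    region_by_probe = ann["region"].to_numpy()
    rho = np.array([cfg.region_correlation[r] for r in region_by_probe])
    subj_ids = sorted(subjects["subject_id"].unique())
    u_dev = {s: 2.0 * np.tanh(rng.normal(0, 1, size=cfg.n_probes) / 2.0)
             for s in subj_ids}

    # -- assemble true betas and channels ----------------------------------
    ref = {"blood": ref_blood.to_numpy(), "csf": ref_csf.to_numpy()}
    cts_map = {"blood": list(BLOOD_CELL_TYPES), "csf": list(CSF_CELL_TYPES)}
    total_base = np.exp(rng.normal(np.log(cfg.mean_total_intensity), 0.3, size=cfg.n_probes))
    design_type = ann["design_type"].to_numpy()
    # bounded dye imbalance (|log| < 2 sd), as for the other array artifacts
    dye_g = np.exp(cfg.dye_bias_sd * 2.0 * np.tanh(rng.normal(0, 1.0, size=n_samples) / 2.0))
    dye_r = np.exp(cfg.dye_bias_sd * 2.0 * np.tanh(rng.normal(0, 1.0, size=n_samples) / 2.0))

    # multimodal probes: per biological identity, a high or low branch
    mm_idx = np.array([probes.index(p) for p in multimodal], dtype=int)
    mm_branch = {key: rng.random(len(mm_idx)) < 0.5 for key in frac_by_key}

    # per-identity noise-free M (replicates share it; re-noised at channel stage)
    M_true = np.empty((cfg.n_probes, n_samples))
    for j, (_, s) in enumerate(sheet.iterrows()):
        if s.is_control_sample:
            beta0 = np.full(cfg.n_probes, float(s.control_beta))
            m = m_from_beta(beta0)
        else:
            key = (s.subject_id, s.tissue, s.collection_day)
            w = frac_by_key[key]
            mix_beta = ref[s.tissue] @ w
            m = m_from_beta(mix_beta)
            e = 2.0 * np.tanh(rng.normal(0, 1, size=cfg.n_probes) / 2.0)
            m = m + cfg.bio_sd * (np.sqrt(rho) * u_dev[s.subject_id]
                                  + np.sqrt(1 - rho) * e)
            m = m + loadings @ factor_scores[j]
            if len(mm_idx):
                # genotype-like multimodality: tight clusters at two levels,
                # not smeared by the biological/latent variation
                branch_beta = np.where(mm_branch[key], 0.85, 0.15)
                m[mm_idx] = (m_from_beta(branch_beta)
                             + rng.normal(0, 0.2, size=len(mm_idx)))
        m = (m + batch["plate"][s.plate] + batch["chip"][s.chip]
             + batch["row"][str(s.row)] + batch["column"][str(s.column)])
        M_true[:, j] = m

    beta_true = beta_from_m(M_true)
    noise_m = np.exp(rng.normal(0, cfg.noise_sigma, size=(cfg.n_probes, n_samples)))
    noise_u = np.exp(rng.normal(0, cfg.noise_sigma, size=(cfg.n_probes, n_samples)))
    bg = cfg.background_mean
    meth = total_base[:, None] * beta_true * noise_m + rng.normal(bg, cfg.background_sd / 2,
                                                                  size=(cfg.n_probes, n_samples))
    unmeth = total_base[:, None] * (1 - beta_true) * noise_u + rng.normal(
        bg, cfg.background_sd / 2, size=(cfg.n_probes, n_samples))
    meth = np.clip(meth, 1.0, None)
    unmeth = np.clip(unmeth, 1.0, None)

    # dye bias by channel: Type II meth=green/unmeth=red; I-green both green;
    # I-red both red
    is_II = design_type == "II"
    is_Ig = design_type == "I-green"
    meth_chan_g = is_II | is_Ig            # else red
    unmeth_chan_g = is_Ig
    meth = meth * np.where(meth_chan_g[:, None], dye_g[None, :], dye_r[None, :])
    unmeth = unmeth * np.where(unmeth_chan_g[:, None], dye_g[None, :], dye_r[None, :])

    beads = rng.poisson(14, size=(cfg.n_probes, n_samples)) + 1

    # -- control probes ----------------------------------------------------
    ctrl_rows = []

    def add_controls(ctype, channel, n, values):
        for i in range(n):
            row = {"control_type": ctype, "channel": channel,
                   "probe_id": f"{ctype}_{channel}_{i + 1:02d}"}
            row.update(dict(zip(sample_ids, np.round(values[i], 3))))
            ctrl_rows.append(row)

    neg_g = rng.normal(cfg.background_mean, cfg.background_sd,
                       size=(cfg.n_negative_controls, n_samples)).clip(1)
    neg_r = rng.normal(cfg.background_mean, cfg.background_sd,
                       size=(cfg.n_negative_controls, n_samples)).clip(1)
    neg_g = neg_g * dye_g[None, :]
    neg_r = neg_r * dye_r[None, :]
    b_sample = np.array([
        batch["plate"][s.plate] + batch["chip"][s.chip]
        + batch["row"][str(s.row)] + batch["column"][str(s.column)]
        for _, s in sheet.iterrows()])
    ctrl_batch = np.power(2.0, 0.5 * b_sample)
    bis_level = cfg.bisulfite_mean * np.exp(
        rng.normal(0, cfg.bisulfite_sample_sd, size=n_samples))
    bis = bis_level[None, :] * ctrl_batch[None, :] * np.exp(
        rng.normal(0, 0.05, size=(cfg.n_bisulfite_controls, n_samples)))
    norm_base = 3000.0
    norm_g = norm_base * np.exp(rng.normal(0, 0.03, size=(cfg.n_norm_controls, n_samples)))
    norm_r = norm_base * np.exp(rng.normal(0, 0.03, size=(cfg.n_norm_controls, n_samples)))
    norm_g = norm_g * dye_g[None, :] * ctrl_batch[None, :]
    norm_r = norm_r * dye_r[None, :] * ctrl_batch[None, :]

    # -- planted failures --------------------------------------------------
    failing = []
    bio_mask = ~sheet["is_control_sample"].astype(bool) & sheet["replicate_group"].isna()
    for tissue, failures in (("csf", cfg.failures_csf), ("blood", cfg.failures_blood)):
        eligible = list(sheet.index[bio_mask & (sheet.tissue == tissue)])
        pick = rng.choice(eligible, size=sum(failures.values()), replace=False)
        it = iter(pick)
        for mode, count in failures.items():
            for _ in range(count):
                j = int(next(it))
                sid = sheet.loc[j, "sample_id"]
                failing.append((sid, mode))
                if mode == "low_bisulfite":
                    bis[:, j] *= 0.15
                elif mode == "high_detection_failure":
                    n_bad = int(0.05 * cfg.n_probes)
                    bad = rng.choice(cfg.n_probes, size=n_bad, replace=False)
                    half = n_bad // 2
                    # half fail by background-level signal, half by bead count
                    meth[bad[:half], j] = rng.normal(bg / 2, cfg.background_sd / 2,
                                                     size=half).clip(1)
                    unmeth[bad[:half], j] = rng.normal(bg / 2, cfg.background_sd / 2,
                                                       size=half).clip(1)
                    beads[bad[half:], j] = 1
                elif mode == "intensity_outlier":
                    meth[:, j] /= 64.0
                    unmeth[:, j] /= 64.0
                elif mode == "beta_outlier":
                    # degenerate mid-range distribution, far from the
                    # bimodal cohort profile by construction
                    ub = rng.uniform(0.35, 0.65, size=cfg.n_probes)
                    tot = meth[:, j] + unmeth[:, j]
                    meth[:, j] = tot * ub
                    unmeth[:, j] = tot * (1 - ub)

    add_controls("negative", "green", cfg.n_negative_controls, neg_g)
    add_controls("negative", "red", cfg.n_negative_controls, neg_r)
    half_b = cfg.n_bisulfite_controls // 2
    add_controls("bisulfite", "green", half_b, bis[:half_b])
    add_controls("bisulfite", "red", cfg.n_bisulfite_controls - half_b, bis[half_b:])
    add_controls("norm_grn", "green", cfg.n_norm_controls, norm_g)
    add_controls("norm_red", "red", cfg.n_norm_controls, norm_r)

    dataset = MethylationDataset(
        meth=pd.DataFrame(np.round(meth, 3), index=probes, columns=sample_ids),
        unmeth=pd.DataFrame(np.round(unmeth, 3), index=probes, columns=sample_ids),
        beads=pd.DataFrame(beads, index=probes, columns=sample_ids),
        controls=pd.DataFrame(ctrl_rows),
        samples=sheet,
    )
    truth = TruthRecord(
        cell_fractions=cell_fractions,
        batch_effects=batch,
        failing_samples=failing,
        multimodal_probes=list(multimodal),
        region_correlation=dict(cfg.region_correlation),
        sv_factors=sv_factors,
        references={"blood": ref_blood, "csf": ref_csf},
        composition_outliers=composition_outliers,
    )
    return dataset, truth, ann


def write_simulation(out_dir, dataset: MethylationDataset, truth: TruthRecord,
                     annotation: pd.DataFrame) -> None:
    from .data_model import write_annotation, write_dataset
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_dataset(dataset, out)
    write_annotation(annotation, out / "annotation.tsv")
    truth.to_json(out / "truth.json")
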