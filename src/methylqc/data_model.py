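"""Core containers, beta/M transforms and tabular IO.

The central object is :class:`MethylationDataset`, which bundles the raw
methylated/unmethylated fluorescence intensity matrices, bead counts,
control-probe intensities and the sample sheet for one study batch.  All
matrices are pandas DataFrames oriented probe x sample; probe and sample
ordering is shared across the matrices and validated on construction.

Methylation level is expressed either as a beta-value
``beta = meth / (meth + unmeth + offset)`` (fraction methylated, in [0, 1])
or as an M-value ``M = log2(beta / (1 - beta))`` (variance-stabilised logit
scale used for all downstream statistics).  The offset (default 100) guards
against instability at low total intensity and is the single beta definition
used everywhere in the package; M is defined as logit2 of that beta.
"""

from __future__ import annotations

import dataclasses
import pathlib
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TISSUES = ("blood", "csf")
CONTROL_TYPES = ("bisulfite", "negative", "norm_grn", "norm_red")
CHANNELS = ("green", "red")
DESIGN_TYPES = ("I-green", "I-red", "II")
REGIONS = ("island", "shore", "shelf", "open_sea")
ORIENTATIONS = ("TSS", "5'UTR", "first_exon", "body", "3'UTR", "intergenic")
CONTROL_BETAS = (0.0, 0.30, 0.70, 1.0)

#: default beta-value intensity offset (Illumina convention)
BETA_OFFSET = 100.0
#: clipping bound applied to beta before the logit2 transform
M_EPS = 1e-6

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "subject_id",
    "tissue",
    "collection_day",
    "plate",
    "chip",
    "row",
    "column",
    "replicate_group",
    "trait",
    "age",
    "sex",
    "is_control_sample",
    "control_beta",
]

ANNOTATION_COLUMNS = [
    "probe_id",
    "design_type",
    "chromosome",
    "region",
    "orientation",
    "snp_overlap",
    "cross_reactive",
]


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def _check_nonneg(x, name: str) -> None:
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} contains negative intensities")


def beta_from_intensities(meth, unmeth, offset: float = BETA_OFFSET):
    """Beta-value from channel intensities: ``meth / (meth + unmeth + offset)``.

    Works elementwise on scalars, arrays or DataFrames; negative intensities
    or a non-positive offset are rejected.
    """
    if offset <= 0:
        raise ValueError("offset must be > 0")
    _check_nonneg(meth, "meth")
    _check_nonneg(unmeth, "unmeth")
    beta = meth / (meth + unmeth + offset)
    return beta


def m_from_beta(beta, eps: float = M_EPS):
    """M-value (logit2 of beta) with epsilon clipping to keep the result finite."""
    b = np.clip(beta, eps, 1.0 - eps)
    return np.log2(b / (1.0 - b))


def beta_from_m(m):
    """Inverse of :func:`m_from_beta` (inverse logit2)."""
    p = np.power(2.0, m)
    return p / (1.0 + p)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BetaMatrix:
    """Probe x sample beta-values with a processing-stage provenance tag."""

    values: pd.DataFrame
    provenance: str = "raw"

    def __post_init__(self):
        v = self.values.to_numpy(dtype=float)
        if np.nanmin(v) < 0 or np.nanmax(v) > 1:
            raise ValueError("beta values must lie in [0, 1]")


@dataclasses.dataclass
class MValueMatrix:
    """Probe x sample M-values with a processing-stage provenance tag."""

    values: pd.DataFrame
    provenance: str = "raw"

    def __post_init__(self):
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("M values must be finite")


def validate_sample_sheet(samples: pd.DataFrame) -> None:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if samples["sample_id"].duplicated().any():
        dups = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    bad_tissue = set(samples["tissue"]) - set(TISSUES)
    if bad_tissue:
        raise ValueError(f"unknown tissue labels: {sorted(bad_tissue)}")
    pos = samples[["plate", "chip", "row", "column"]]
    if pos.duplicated().any():
        dup = pos[pos.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate plate position: {dup}")
    # technical replicates must agree on what was re-assayed
    grouped = samples.dropna(subset=["replicate_group"]).groupby("replicate_group")
    for name, grp in grouped:
        for col in ("subject_id", "tissue", "collection_day"):
            if grp[col].nunique(dropna=False) > 1:
                raise ValueError(
                    f"replicate group {name!r} members disagree on {col}"
                )
    ctrl = samples[samples["is_control_sample"].astype(bool)]
    bad_beta = set(np.round(ctrl["control_beta"].astype(float), 6)) - set(CONTROL_BETAS)
    if bad_beta:
        raise ValueError(f"control samples must have fixed beta in {CONTROL_BETAS}")


def validate_annotation(annotation: pd.DataFrame) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    for col, allowed in (
        ("design_type", DESIGN_TYPES),
        ("region", REGIONS),
        ("orientation", ORIENTATIONS),
    ):
        bad = set(annotation[col]) - set(allowed)
        if bad:
            raise ValueError(f"annotation column {col} has unknown values: {sorted(bad)}")


@dataclasses.dataclass
class MethylationDataset:
    """Raw two-channel intensity data plus metadata for one batch of arrays.

    Attributes
    ----------
    meth, unmeth : DataFrame, probe x sample, non-negative intensities.
    beads : DataFrame, probe x sample, non-negative integer bead counts.
    controls : DataFrame with columns ``control_type`` (bisulfite, negative,
        norm_grn, norm_red), ``channel`` (green, red), ``probe_id``, and one
        intensity column per sample.
    samples : sample sheet DataFrame (see ``SAMPLE_SHEET_COLUMNS``).
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    beads: pd.DataFrame
    controls: pd.DataFrame
    samples: pd.DataFrame
    #: processing stages already applied (e.g. "background", "dye_bias")
    stages: list = dataclasses.field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for name, mat in (("unmeth", self.unmeth), ("beads", self.beads)):
            if not mat.index.equals(self.meth.index):
                raise ValueError(f"{name} probe index differs from meth")
            if not mat.columns.equals(self.meth.columns):
                raise ValueError(f"{name} sample columns differ from meth")
        for name, mat in (("meth", self.meth), ("unmeth", self.unmeth), ("beads", self.beads)):
            _check_nonneg(mat.to_numpy(), name)
        validate_sample_sheet(self.samples)
        sheet_ids = list(self.samples["sample_id"])
        matrix_ids = list(self.meth.columns)
        missing = sorted(set(matrix_ids) - set(sheet_ids))
        extra = sorted(set(sheet_ids) - set(matrix_ids))
        if missing:
            raise ValueError(f"samples in matrices but not in sample sheet: {missing}")
        if extra:
            raise ValueError(f"samples in sample sheet but not in matrices: {extra}")
        ctrl_meta = {"control_type", "channel", "probe_id"}
        if not ctrl_meta <= set(self.controls.columns):
            raise ValueError("controls table needs control_type, channel, probe_id columns")
        ctrl_samples = [c for c in self.controls.columns if c not in ctrl_meta]
        if sorted(ctrl_samples) != sorted(matrix_ids):
            raise ValueError("controls table sample columns do not match matrices")

    # -- convenience -------------------------------------------------------
    @property
    def probes(self) -> pd.Index:
        return self.meth.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meth.columns)

    def total_intensity(self) -> pd.DataFrame:
        return self.meth + self.unmeth

    def beta(self, offset: float = BETA_OFFSET) -> pd.DataFrame:
        return beta_from_intensities(self.meth, self.unmeth, offset)

    def mvalues(self, offset: float = BETA_OFFSET) -> pd.DataFrame:
        return m_from_beta(self.beta(offset))

    def control_intensities(self, control_type: str, channel: str | None = None) -> pd.DataFrame:
        """Control-probe intensities (rows: control probes, cols: samples)."""
        mask = self.controls["control_type"] == control_type
        if channel is not None:
            mask &= self.controls["channel"] == channel
        sub = self.controls[mask]
        return sub.set_index("probe_id")[self.sample_ids]

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationDataset":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        meta = ["control_type", "channel", "probe_id"]
        return MethylationDataset(
            meth=self.meth[keep].copy(),
            unmeth=self.unmeth[keep].copy(),
            beads=self.beads[keep].copy(),
            controls=self.controls[meta + keep].copy(),
            samples=self.samples[self.samples["sample_id"].isin(keep)].reset_index(drop=True),
            stages=list(self.stages),
        )

    def subset_probes(self, probe_ids: Sequence[str]) -> "MethylationDataset":
        keep = [p for p in self.probes if p in set(probe_ids)]
        return MethylationDataset(
            meth=self.meth.loc[keep].copy(),
            unmeth=self.unmeth.loc[keep].copy(),
            beads=self.beads.loc[keep].copy(),
            controls=self.controls.copy(),
            samples=self.samples.copy(),
            stages=list(self.stages),
        )

    def copy(self) -> "MethylationDataset":
        return MethylationDataset(
            meth=self.meth.copy(),
            unmeth=self.unmeth.copy(),
            beads=self.beads.copy(),
            controls=self.controls.copy(),
            samples=self.samples.copy(),
            stages=list(self.stages),
        )


# ---------------------------------------------------------------------------
# IO: TSV matrices, CSV sample sheet, TSV annotation (gzip transparent)
# ---------------------------------------------------------------------------

_MATRIX_FILES = ("meth", "unmeth", "beads")


def _find(directory: pathlib.Path, stem: str, ext: str) -> pathlib.Path:
    for suffix in (ext, ext + ".gz"):
        p = directory / (stem + suffix)
        if p.exists():
            return p
    raise FileNotFoundError(f"no {stem}{ext}[.gz] in {directory}")


def write_matrix(mat: pd.DataFrame, path) -> None:
    """Write a probe x sample matrix as TSV with a leading probe_id column."""
    out = mat.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def write_annotation(annotation: pd.DataFrame, path) -> None:
    ann = annotation.reset_index() if "probe_id" not in annotation.columns else annotation
    ann[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    validate_annotation(ann)
    return ann.set_index("probe_id", drop=False)


def write_dataset(dataset: MethylationDataset, directory, gzip: bool = False) -> None:
    """Persist a dataset as plain-text tables under ``directory``."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzip else ""
    for name in _MATRIX_FILES:
        write_matrix(getattr(dataset, name), directory / f"{name}.tsv{suffix}")
    dataset.controls.to_csv(directory / f"controls.tsv{suffix}", sep="\t", index=False)
    dataset.samples.to_csv(directory / f"samples.csv{suffix}", index=False)
    if dataset.stages:
        (directory / "stages.txt").write_text("\n".join(dataset.stages) + "\n")


def read_dataset(directory) -> MethylationDataset:
    """Read a dataset written by :func:`write_dataset` (gzip transparent)."""
    directory = pathlib.Path(directory)
    mats = {name: read_matrix(_find(directory, name, ".tsv")) for name in _MATRIX_FILES}
    controls = pd.read_csv(_find(directory, "controls", ".tsv"), sep="\t")
    samples = pd.read_csv(_find(directory, "samples", ".csv"))
    stages_file = directory / "stages.txt"
    stages = stages_file.read_text().split() if stages_file.exists() else []
    return MethylationDataset(controls=controls, samples=samples, stages=stages, **mats)
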