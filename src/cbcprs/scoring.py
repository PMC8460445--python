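"""PRS computation: allele alignment, weighted scoring and standardization.

The score for subject j is ``raw_j = sum_i w_i g_ij`` where ``g_ij`` is the
effect-allele dosage (0..2, fractional for imputed genotypes) and ``w_i`` the
per-allele log odds ratio from the weight panel.  Three flavours (overall,
ER-positive, ER-negative) share variants but differ in weights.  Scores are
reported in SD units of an external reference population: centred on the mean
of the full analysis cohort (affected and unaffected alike) and divided by a
user-supplied reference SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StandardizationSpec",
    "read_weight_panel",
    "read_dosage_csv",
    "read_dosage_vcf",
    "align_dosages",
    "compute_prs",
    "standardize_prs",
    "score_pipeline",
]

FLAVOR_COLUMNS = {
    "overall": "weight_overall",
    "er_positive": "weight_erpos",
    "er_negative": "weight_erneg",
}

WEIGHT_HEADER = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "weight_overall",
    "weight_erpos",
    "weight_erneg",
]

_AMBIGUOUS_PAIRS = {frozenset("AT"), frozenset("CG")}


@dataclass
class StandardizationSpec:
    """Centre/scale contract for reporting PRS in reference-SD units.

    ``scale`` is the SD of the raw score in an external reference population
    (e.g. population controls); it has no default because it is a property of
    the weight panel and reference sample, not of the analysis cohort.
    ``center=None`` requests internal centring on the mean over all subjects
    supplied, cases and non-cases alike.
    """

    scale: float
    center: float | None = None

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def read_weight_panel(path: str | Path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t")
    missing = set(WEIGHT_HEADER) - set(panel.columns)
    if missing:
        raise ValueError(f"weight table missing columns: {sorted(missing)}")
    if panel["variant_id"].duplicated().any():
        raise ValueError("duplicate variant ids in weight table")
    if ((panel["eaf"] <= 0) | (panel["eaf"] >= 1)).any():
        raise ValueError("effect-allele frequencies must lie strictly in (0, 1)")
    panel["chrom"] = panel["chrom"].astype(str)
    return panel


def read_dosage_csv(path: str | Path) -> pd.DataFrame:
    """Subject x variant dosage matrix; first column is the subject id."""
    geno = pd.read_csv(path, index_col=0)
    geno.index.name = "subject_id"
    return geno


def read_dosage_vcf(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF carrying a DS FORMAT field.

    Returns (dosages, source_meta) where dosages holds ALT-allele expected
    counts and source_meta records each variant's coded (ALT) and other (REF)
    allele plus the empirical coded-allele frequency, as needed for alignment.
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, coded, other, freqs, rows = [], [], [], [], []
    for var in vcf:
        ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        ids.append(var.ID)
        coded.append(var.ALT[0])
        other.append(var.REF)
        freqs.append(float(np.nanmean(ds)) / 2.0)
        rows.append(ds)
    dosages = pd.DataFrame(
        np.asarray(rows).T, index=pd.Index(samples, name="subject_id"), columns=ids
    )
    meta = pd.DataFrame(
        {
            "variant_id": ids,
            "coded_allele": coded,
            "other_allele": other,
            "coded_freq": freqs,
        }
    )
    return dosages, meta


def align_dosages(
    panel: pd.DataFrame,
    dosages: pd.DataFrame,
    source_meta: pd.DataFrame,
    freq_diff_limit: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Orient source dosages to the panel's effect allele.

    A variant whose coded allele equals the panel effect allele passes
    through; one whose coded allele equals the panel other allele is flipped
    (d -> 2 - d).  Variants whose allele pair does not match the panel are
    dropped.  Strand-ambiguous pairs (A/T, C/G) cannot be oriented from
    alleles alone, so they are dropped when the source coded-allele frequency
    differs from the panel effect-allele frequency by more than
    ``freq_diff_limit``.

    Returns (aligned dosages, per-variant alignment log).
    """
    if source_meta["variant_id"].duplicated().any():
        raise ValueError("duplicate variant ids in source dosages")
    meta = source_meta.set_index("variant_id")
    aligned = {}
    log_rows = []
    for row in panel.itertuples(index=False):
        vid = row.variant_id
        if vid not in meta.index or vid not in dosages.columns:
            log_rows.append((vid, "absent_from_source"))
            continue
        coded = meta.at[vid, "coded_allele"]
        other = meta.at[vid, "other_allele"]
        pair = frozenset((coded, other))
        if pair != frozenset((row.effect_allele, row.other_allele)):
            log_rows.append((vid, "allele_pair_mismatch"))
            continue
        if pair in _AMBIGUOUS_PAIRS:
            src_freq = meta.at[vid, "coded_freq"]
            if abs(src_freq - row.eaf) > freq_diff_limit:
                log_rows.append((vid, "strand_ambiguous_freq_mismatch"))
                continue
        if coded == row.effect_allele:
            aligned[vid] = dosages[vid]
            log_rows.append((vid, "kept"))
        else:
            aligned[vid] = 2.0 - dosages[vid]
            log_rows.append((vid, "flipped"))
    log = pd.DataFrame(log_rows, columns=["variant_id", "action"])
    n_dropped = (~log["action"].isin(["kept", "flipped"])).sum()
    if n_dropped:
        logger.info("align_dosages dropped %d variants", n_dropped)
    return pd.DataFrame(aligned, index=dosages.index), log


def compute_prs(
    dosages: pd.DataFrame,
    panel: pd.DataFrame,
    flavor: str = "overall",
    max_missing_fraction: float = 0.2,
) -> pd.DataFrame:
    """Raw weighted-sum scores for one PRS flavour.

    Missing dosages are mean-imputed at twice the panel effect-allele
    frequency (the expected dosage under HWE).  Subjects missing more than
    ``max_missing_fraction`` of panel variants are flagged, not dropped.
    Variants in the dosage matrix but absent from the panel are ignored with
    a warning.
    """
    if flavor not in FLAVOR_COLUMNS:
        raise ValueError(f"unknown PRS flavor {flavor!r}")
    panel = panel.set_index("variant_id")
    extra = [c for c in dosages.columns if c not in panel.index]
    if extra:
        logger.warning("%d dosage variants absent from panel; ignored", len(extra))
    shared = [v for v in panel.index if v in dosages.columns]
    if not shared:
        raise ValueError("no panel variants present in dosages")

    mat = dosages[shared].to_numpy(dtype=float)
    weights = panel.loc[shared, FLAVOR_COLUMNS[flavor]].to_numpy()
    fill = 2.0 * panel.loc[shared, "eaf"].to_numpy()

    missing = np.isnan(mat)
    n_imputed = missing.sum(axis=1)
    if n_imputed.sum():
        logger.info("mean-imputed %d missing dosages at 2p", int(n_imputed.sum()))
    mat = np.where(missing, fill, mat)

    return pd.DataFrame(
        {
            "subject_id": dosages.index,
            "raw_score": mat @ weights,
            "n_variants_imputed": n_imputed,
            "high_missingness": n_imputed > max_missing_fraction * len(shared),
            "prs_flavor": flavor,
        }
    ).set_index("subject_id")


def standardize_prs(
    raw_scores: pd.Series | np.ndarray, spec: StandardizationSpec
) -> tuple[np.ndarray, StandardizationSpec]:
    """Map raw scores to z = (raw - center) / scale.

    With ``spec.center=None`` the centre is the mean over every score
    supplied; the resolved spec is returned alongside z so the affine map is
    reproducible on new subjects.
    """
    raw = np.asarray(raw_scores, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw scores must be finite")
    center = float(raw.mean()) if spec.center is None else spec.center
    z = (raw - center) / spec.scale
    return z, StandardizationSpec(scale=spec.scale, center=center)


def score_pipeline(
    panel: pd.DataFrame,
    dosages: pd.DataFrame,
    spec: StandardizationSpec,
    flavor: str = "overall",
    source_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Align (when source allele metadata is given), score and standardize."""
    if source_meta is not None:
        dosages, _ = align_dosages(panel, dosages, source_meta)
    scores = compute_prs(dosages, panel, flavor=flavor)
    z, resolved = standardize_prs(scores["raw_score"], spec)
    scores = scores.assign(z=z)
    scores.attrs["standardization"] = {"center": resolved.center, "scale": resolved.scale}
    return scores
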