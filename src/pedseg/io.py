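"""Readers and writers for annotated VCF, pedigree, gene-list and TSV files.

VCF parsing is delegated to :mod:`cyvcf2`; this module only normalizes
records into :class:`~pedseg.datamodel.AnnotatedVariant` (splitting
multi-allelic sites, decoding genotypes to allele counts, mapping the
configurable INFO keys onto the typed annotation fields).

The pedigree format is standard 6-column PED extended with a mandatory
7th column giving the sample role (``case`` / ``family_control`` /
``unrelated_control``): the three-way role split of a familial
case-control design is not expressible in plain PED affection coding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datamodel import (
    MISSING_GT,
    PREDICTOR_NAMES,
    AnnotatedVariant,
    Cohort,
    Consequence,
    Diagnosis,
    GeneSet,
    PredictorCall,
    Role,
    Sample,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationKeys",
    "read_annotated_vcf",
    "read_pedigree",
    "read_gene_list",
    "variants_to_frame",
    "write_variant_table",
    "read_variant_table",
]


@dataclass
class AnnotationKeys:
    """Mapping from logical annotation fields to VCF INFO keys.

    Annotation key names vary across annotator versions, so the mapping is
    configuration, not convention.
    """

    gene: str = "GENE"
    consequence: str = "CSQ"
    maf_sas: str = "AF_SAS"
    maf_global: str = "AF_GLOBAL"
    predictors: tuple[str, ...] = ("SIFT", "LRT", "MT", "MA", "MSVM")

    def __post_init__(self) -> None:
        if len(self.predictors) != len(PREDICTOR_NAMES):
            raise ValueError(
                f"expected {len(PREDICTOR_NAMES)} predictor keys, "
                f"got {len(self.predictors)}"
            )


def _info_for_alt(value, alt_index: int, n_alts: int):
    """Pick the per-ALT slice of an INFO value on a multi-allelic record."""
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        return value[alt_index] if len(value) == n_alts else value[0]
    if isinstance(value, str) and n_alts > 1 and value.count(",") == n_alts - 1:
        return value.split(",")[alt_index]
    return value


def _parse_maf(raw, where: str) -> float | None:
    if raw is None:
        return None
    if isinstance(raw, (float, np.floating)):
        val = float(raw)
    else:
        text = str(raw).strip()
        if text in ("", ".", "NA", "nan"):
            return None
        try:
            val = float(text)
        except ValueError:
            raise ValueError(f"unparsable allele frequency {raw!r} at {where}") from None
    if np.isnan(val):
        return None
    if not 0.0 <= val <= 1.0:
        raise ValueError(f"allele frequency {val} outside [0, 1] at {where}")
    return val


def _parse_predictor(raw) -> PredictorCall:
    if raw is None:
        return PredictorCall.MISSING
    text = str(raw).strip().upper()
    if text in ("D", "DELETERIOUS"):
        return PredictorCall.DELETERIOUS
    if text in ("T", "TOLERATED", "N", "B"):
        return PredictorCall.TOLERATED
    return PredictorCall.MISSING


def read_annotated_vcf(
    path: str | Path,
    cohort: Cohort,
    keys: AnnotationKeys | None = None,
) -> list[AnnotatedVariant]:
    """Read an annotated multi-sample VCF into normalized biallelic variants.

    Multi-allelic records are split into one variant per ALT allele;
    genotypes become per-sample counts of that specific allele. A variant
    annotated to several genes (comma- or semicolon-separated symbol list)
    is expanded to one record per gene so gene-level analyses see per-gene
    rows. Missing annotations stay missing.

    Raises
    ------
    ValueError
        If the VCF sample set differs from the cohort, or an allele
        frequency fails to parse (the error names the offending record).
    """
    keys = keys or AnnotationKeys()
    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    cohort_ids = set(cohort.sample_ids)
    extra = [s for s in vcf_samples if s not in cohort_ids]
    if extra:
        raise ValueError(f"VCF samples absent from cohort: {extra}")
    missing = [s for s in cohort.sample_ids if s not in vcf_samples]
    if missing:
        raise ValueError(f"cohort samples absent from VCF: {missing}")
    # permutation taking VCF column order to cohort order
    order = np.array(
        [vcf_samples.index(sid) for sid in cohort.sample_ids], dtype=np.intp
    )

    out: list[AnnotatedVariant] = []
    for rec in vcf:
        alts = rec.ALT
        n_alts = len(alts)
        gts = np.array([g[:2] for g in rec.genotypes], dtype=np.int32)
        for ai, alt in enumerate(alts):
            allele_code = ai + 1
            counts = (gts == allele_code).sum(axis=1).astype(np.int8)
            counts[(gts < 0).any(axis=1)] = MISSING_GT
            counts = counts[order]

            where = f"{rec.CHROM}:{rec.POS}"
            raw_gene = _info_for_alt(rec.INFO.get(keys.gene), ai, n_alts)
            raw_csq = _info_for_alt(rec.INFO.get(keys.consequence), ai, n_alts)
            maf_sas = _parse_maf(
                _info_for_alt(rec.INFO.get(keys.maf_sas), ai, n_alts), where
            )
            maf_global = _parse_maf(
                _info_for_alt(rec.INFO.get(keys.maf_global), ai, n_alts), where
            )
            calls = tuple(
                _parse_predictor(_info_for_alt(rec.INFO.get(k), ai, n_alts))
                for k in keys.predictors
            )
            try:
                csq = Consequence(str(raw_csq)) if raw_csq else Consequence.OTHER
            except ValueError:
                csq = Consequence.OTHER
            genes = str(raw_gene or ".").replace(";", ",").split(",")
            for gene in genes:
                out.append(
                    AnnotatedVariant(
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        gene=gene.strip(),
                        consequence=csq,
                        maf_sas=maf_sas,
                        maf_global=maf_global,
                        predictor_calls=calls,
                        genotypes=counts,
                    )
                )
    vcf.close()
    return out


_ROLE_CODES = {
    "case": Role.CASE,
    "family_control": Role.FAMILY_CONTROL,
    "unrelated_control": Role.UNRELATED_CONTROL,
}


def read_pedigree(path: str | Path) -> Cohort:
    """Read a 7-column PED file (family, id, father, mother, sex, affection, role).

    Affection uses PED coding (2 affected, 1 unaffected, 0/-9 unknown).
    Family id "0" together with role ``unrelated_control`` denotes a
    population control outside any family. An optional 8th column carries
    the diagnosis label of affected samples.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 7:
            raise ValueError(f"{path}:{lineno}: expected >= 7 columns, got {len(parts)}")
        rows.append((lineno, parts))

    samples: list[Sample] = []
    seen: set[str] = set()
    by_family: dict[str, set[str]] = {}
    for lineno, parts in rows:
        fid, sid, father, mother, sex, aff, role = parts[:7]
        if sid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate sample id {sid!r}")
        seen.add(sid)
        if role not in _ROLE_CODES:
            raise ValueError(f"{path}:{lineno}: unknown role {role!r}")
        fid = "" if fid in ("0", "") else fid
        diagnosis = None
        if len(parts) >= 8 and parts[7] not in (".", "0", ""):
            diagnosis = Diagnosis(parts[7])
        samples.append(
            Sample(
                sample_id=sid,
                family_id=fid,
                father_id=None if father in ("0", "") else father,
                mother_id=None if mother in ("0", "") else mother,
                sex=int(sex) if sex in ("1", "2") else 0,
                affected=aff == "2",
                role=_ROLE_CODES[role],
                diagnosis=diagnosis,
            )
        )
        if fid:
            by_family.setdefault(fid, set()).add(sid)

    # Parent links must resolve within the same family when the parent was
    # sequenced; unsequenced parents are encoded as "0" and skipped above.
    for s in samples:
        for pid in (s.father_id, s.mother_id):
            if pid is not None and pid not in by_family.get(s.family_id, set()):
                raise ValueError(
                    f"sample {s.sample_id}: parent {pid!r} not found in "
                    f"family {s.family_id!r}"
                )
    return Cohort(samples=samples)


def read_gene_list(path: str | Path, name: str, universe_size: int) -> GeneSet:
    """Read a one-symbol-per-line gene list into a deduplicated GeneSet."""
    symbols = {
        line.strip().upper()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
    if not symbols:
        raise ValueError(f"gene list {path} is empty")
    return GeneSet(name=name, genes=frozenset(symbols), universe_size=universe_size)


# -- tabular variant round-trip ---------------------------------------------


def variants_to_frame(variants: list[AnnotatedVariant], cohort: Cohort) -> pd.DataFrame:
    """Flatten variants to a DataFrame with one genotype column per sample."""
    rows = []
    for v in variants:
        row = {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "consequence": v.consequence.value,
            "maf_sas": np.nan if v.maf_sas is None else v.maf_sas,
            "maf_global": np.nan if v.maf_global is None else v.maf_global,
        }
        for pname, call in zip(PREDICTOR_NAMES, v.predictor_calls):
            row[pname] = call.value
        for sid, gt in zip(cohort.sample_ids, v.genotypes):
            row[f"gt:{sid}"] = int(gt)
        rows.append(row)
    return pd.DataFrame(rows)


def write_variant_table(
    variants: list[AnnotatedVariant],
    cohort: Cohort,
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    frame = variants_to_frame(variants, cohort)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_variant_table(path: str | Path, cohort: Cohort) -> list[AnnotatedVariant]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    gt_cols = [f"gt:{sid}" for sid in cohort.sample_ids]
    out = []
    for _, row in frame.iterrows():
        out.append(
            AnnotatedVariant(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                gene=str(row["gene"]),
                consequence=Consequence(row["consequence"]),
                maf_sas=None if pd.isna(row["maf_sas"]) else float(row["maf_sas"]),
                maf_global=(
                    None if pd.isna(row["maf_global"]) else float(row["maf_global"])
                ),
                predictor_calls=tuple(
                    PredictorCall(str(row[p])) for p in PREDICTOR_NAMES
                ),
                genotypes=np.array([row[c] for c in gt_cols], dtype=np.int8),
            )
        )
    return out
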