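"""Reading and writing of external formats, configuration and logging.

Genotypes arrive either as a biallelic-SNP VCF (parsed with cyvcf2) or as a
delimited dosage table (lines x markers, 0/1/2 alternate-allele counts).
Phenotypes arrive as long or wide CSV over a days-after-sowing axis; the
block/gap structure of the measurement design is inferred from the calendar
days (a jump of more than one day starts a new block).

Missing genotype calls are an error: genotype imputation belongs upstream of
this package. Missing phenotypes are an error unless mean imputation is
explicitly requested via :func:`mean_impute_tensor`.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import GenotypeMatrix, TraitTensor

__all__ = [
    "read_genotype_matrix",
    "filter_by_maf",
    "read_trait_tensor",
    "mean_impute_tensor",
    "write_prediction_report",
    "read_prediction_report",
    "write_grm_csv",
    "read_grm_csv",
    "load_config",
    "DEFAULT_CONFIG",
    "setup_logging",
]

logger = logging.getLogger("dmdgp")

#: Default run configuration; every CLI flag has a twin here and the CLI wins.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "genotypes": {"min_maf": 0.05, "impute_missing_phenotypes": False},
    "trait_selection": {"mantel_threshold": 0.96, "absolute_mantel": False},
    "dmd": {"rank": 2, "gap_policy": "unit_step"},
    "cv": {"n_iterations": 20, "n_folds": 5, "validation_fraction": 0.0},
    "rank_selection": {"candidates": [2, 3, 4, 5, 6], "predictability_floor": 0.1},
}


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config file, filling unset keys from :data:`DEFAULT_CONFIG`."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(section), dict):
                cfg[section].update(value)
            else:
                cfg[section] = value
    return cfg


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown (with gts012=False
        # cyvcf2 uses 2=unknown/3=hom-alt; re-read genotypes explicitly)
        gts = np.array([g[:2] for g in rec.genotypes])  # (k, 2) allele indices
        if (gts < 0).any():
            bad = int(np.flatnonzero((gts < 0).any(axis=1))[0])
            raise ValueError(
                f"missing genotype call for line {line_ids[bad]!r} at marker "
                f"{rec.ID or f'{rec.CHROM}:{rec.POS}'!r}; impute genotypes upstream"
            )
        marker_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        rows.append(gts.sum(axis=1))
    if n_skipped:
        logger.info("skipped %d non-biallelic/non-SNP VCF records", n_skipped)
    if not rows:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    return GenotypeMatrix(line_ids, marker_ids, np.column_stack(rows))


def _read_dosage_table(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    line_ids = [str(i) for i in df.index]
    marker_ids = [str(c) for c in df.columns]
    values = df.to_numpy()
    for (i, j) in zip(*np.nonzero(pd.isna(df).to_numpy())):
        raise ValueError(
            f"missing dosage for line {line_ids[i]!r}, marker {marker_ids[j]!r}"
        )
    rounded = np.round(values.astype(float))
    bad = np.nonzero(np.abs(values.astype(float) - rounded) > 1e-9)
    if bad[0].size:
        i, j = bad[0][0], bad[1][0]
        raise ValueError(
            f"non-integer dosage {values[i, j]!r} for line {line_ids[i]!r}, "
            f"marker {marker_ids[j]!r}"
        )
    return GenotypeMatrix(line_ids, marker_ids, rounded.astype(np.int64))


def read_genotype_matrix(path: str | Path, format: str = "dosage_table") -> GenotypeMatrix:
    """Read SNP dosages from a VCF or a delimited dosage table.

    VCF records that are not biallelic SNPs are skipped (count logged).
    Any missing genotype call is an error naming the line and marker.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_table":
        return _read_dosage_table(path)
    raise ValueError(f"unknown genotype format {format!r}")


def filter_by_maf(G: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Drop markers with minor-allele frequency below ``min_maf`` (order kept)."""
    if not 0 <= min_maf < 0.5:
        raise ValueError("min_maf must be in [0, 0.5)")
    keep = G.maf >= min_maf
    if not keep.any():
        raise ValueError(
            f"all {G.n_markers} markers have MAF < {min_maf}; lower the threshold"
        )
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("MAF filter removed %d of %d markers", n_dropped, G.n_markers)
    return G.subset_markers(keep)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _assemble_tensor(df: pd.DataFrame) -> TraitTensor:
    """Build a TraitTensor from a long table with columns line/trait/day/value."""
    lines = sorted(df["line"].astype(str).unique())
    traits = sorted(df["trait"].astype(str).unique())
    days = np.array(sorted(df["day"].astype(int).unique()))
    key = df[["line", "trait", "day"]].astype(str).agg("|".join, axis=1)
    dup = key[key.duplicated()]
    if len(dup):
        raise ValueError(f"duplicated (line, trait, day) combinations, e.g. {dup.iloc[0]!r}")
    expected = len(lines) * len(traits) * len(days)
    if len(df) != expected:
        have = set(key)
        missing = [
            f"({l}, {t}, {d})"
            for l in lines for t in traits for d in days
            if f"{l}|{t}|{d}" not in have
        ]
        raise ValueError(
            f"{len(missing)} missing (line, trait, day) combinations: "
            + "; ".join(missing[:10])
        )
    li = {l: i for i, l in enumerate(lines)}
    ti = {t: i for i, t in enumerate(traits)}
    di = {d: i for i, d in enumerate(days)}
    values = np.full((len(lines), len(traits), len(days)), np.nan)
    values[
        df["line"].astype(str).map(li),
        df["trait"].astype(str).map(ti),
        df["day"].astype(int).map(di),
    ] = df["value"].to_numpy(dtype=float)
    return TraitTensor(lines, traits, days, values)


def read_trait_tensor(path: str | Path, layout: str = "long") -> TraitTensor:
    """Read time-resolved phenotypes from CSV.

    ``long`` layout: columns (line, trait, day, value).
    ``wide`` layout: columns (line, trait, <day>, <day>, ...), one row per
    line x trait, one column per calendar day.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "long":
        df = pd.read_csv(path)
        required = {"line", "trait", "day", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"long layout needs columns {sorted(required)}")
        return _assemble_tensor(df)
    if layout == "wide":
        df = pd.read_csv(path)
        if not {"line", "trait"}.issubset(df.columns):
            raise ValueError("wide layout needs 'line' and 'trait' columns plus day columns")
        day_cols = [c for c in df.columns if c not in ("line", "trait")]
        long = df.melt(
            id_vars=["line", "trait"], value_vars=day_cols,
            var_name="day", value_name="value",
        )
        long["day"] = long["day"].astype(int)
        return _assemble_tensor(long)
    raise ValueError(f"unknown phenotype layout {layout!r}")


def mean_impute_tensor(t: TraitTensor) -> TraitTensor:
    """Replace NaN entries by the across-line mean of the same trait x day.

    A deliberately simple utility: a trait x day slice that is entirely
    missing cannot be imputed and raises.
    """
    values = t.values.copy()
    missing = np.isnan(values)
    if not missing.any():
        return t
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(values, axis=0)  # (p, T)
    dead = np.isnan(col_mean)
    if dead.any():
        pi, ti = np.argwhere(dead)[0]
        raise ValueError(
            f"trait {t.trait_ids[pi]!r} at day {int(t.time_axis[ti])} is entirely missing"
        )
    filled = np.where(missing, np.broadcast_to(col_mean, values.shape), values)
    logger.info("mean-imputed %d missing phenotype values", int(missing.sum()))
    return TraitTensor(
        list(t.line_ids), list(t.trait_ids), t.time_axis.copy(), filled,
        [b.copy() for b in t.blocks],
    )


# ---------------------------------------------------------------------------
# reports and matrices
# ---------------------------------------------------------------------------

def _matrix_frame(matrix: np.ndarray, trait_ids, time_axis) -> pd.DataFrame:
    return pd.DataFrame(
        matrix, index=list(trait_ids), columns=[str(int(d)) for d in time_axis]
    )


def write_prediction_report(result, path: str | Path) -> list[Path]:
    """Write accuracy/MSE tables and run metadata for a PredictionResult.

    CSV floats are written with ``repr`` precision so a round-trip read
    reproduces the tables bit-exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for name, mat in (
        ("accuracy", result.accuracy),
        ("accuracy_sd", result.accuracy_sd),
        ("mse", result.mse),
    ):
        out = path / f"{name}.csv"
        _matrix_frame(mat, result.trait_ids, result.time_axis).to_csv(
            out, float_format=lambda v: repr(float(v))
        )
        written.append(out)
    meta = path / "run_metadata.json"
    with open(meta, "w") as fh:
        json.dump(result.metadata, fh, indent=2, sort_keys=True)
    written.append(meta)
    return written


def read_prediction_report(path: str | Path) -> dict:
    """Read back the tables written by :func:`write_prediction_report`."""
    path = Path(path)
    out = {}
    for name in ("accuracy", "accuracy_sd", "mse"):
        df = pd.read_csv(path / f"{name}.csv", index_col=0,
                         float_precision="round_trip")
        out[name] = df.to_numpy()
        out["trait_ids"] = [str(i) for i in df.index]
        out["time_axis"] = np.array([int(c) for c in df.columns])
    with open(path / "run_metadata.json") as fh:
        out["metadata"] = json.load(fh)
    return out


def write_grm_csv(grm, path: str | Path) -> None:
    pd.DataFrame(grm.K, index=grm.line_ids, columns=grm.line_ids).to_csv(path)


def read_grm_csv(path: str | Path):
    from .markers import GRM

    df = pd.read_csv(path, index_col=0)
    K = df.to_numpy()
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("GRM read from CSV is not symmetric")
    return GRM([str(i) for i in df.index], K)
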