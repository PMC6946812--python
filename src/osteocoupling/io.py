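"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions
-----------
* Counts: TSV, first column ``gene_id``, header row of sample IDs, integer
  cells, no quoting.
* Gene annotation: TSV with columns ``gene_id``, ``gc_fraction``,
  ``length_bp``, ``secreted`` (0/1).
* Sample metadata: TSV with columns ``sample_id``, ``subject_id``, ``group``
  (``placebo`` or ``treated``).
* Gene sets: GMT — one set per line, ``name<TAB>description<TAB>gene...``.
* NPX proteomics: CSV, proteins as rows, samples as columns, log2 scale.
* Serum markers: CSV in long form with columns ``subject_id``, ``marker``,
  ``timepoint``, ``value``.

Gene identifiers are opaque, case-sensitive strings; any symbol/accession
mapping is the caller's responsibility.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("osteocoupling")

GROUP_LABELS = ("placebo", "treated")


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene identifiers (one GMT record)."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def intersect(self, universe: Iterable[str]) -> "GeneSet":
        """Restrict to genes present in *universe*, preserving order."""
        allowed = set(universe)
        kept = tuple(g for g in self.genes if g in allowed)
        dropped = len(self.genes) - len(kept)
        if dropped:
            logger.warning(
                "gene set %s: %d member(s) absent from the universe were dropped",
                self.name, dropped,
            )
        return GeneSet(self.name, kept, self.description)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Read a GMT file into an ordered mapping of name -> GeneSet.

    Duplicate genes within a record are deduplicated (first occurrence wins)
    with a logged warning.  A line with fewer than two tab-separated fields
    is a format error naming the line number.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}: line {lineno}: GMT records need at least "
                    f"name and description fields"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                logger.warning(
                    "%s: line %d: set %r contains %d duplicated gene id(s); "
                    "deduplicated", path, lineno, name, len(genes) - len(unique),
                )
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = GeneSet(name, tuple(unique), description)
    return sets


def write_gmt(sets: Mapping[str, GeneSet] | Iterable[GeneSet], path: str | Path) -> None:
    records = sets.values() if isinstance(sets, Mapping) else sets
    with open(path, "w") as fh:
        for gs in records:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# Count matrices and annotation
# ---------------------------------------------------------------------------

def _check_unique(index: pd.Index, what: str, path: str | Path) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()[:5]
        raise FormatError(f"{path}: duplicate {what}: {dups}")


def read_counts(
    path: str | Path, annotation_path: str | Path | None = None
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Read a gene x sample integer count matrix (and optional annotation).

    Every cell must be a non-negative integer; a fractional or negative cell
    is reported with its gene and sample coordinates.  When
    *annotation_path* is given the annotation must cover every gene in the
    count matrix and the pair ``(counts, annotation)`` is returned, with the
    annotation reindexed to the count-matrix gene order.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(df.index, "gene ids", path)
    _check_unique(df.columns, "sample ids", path)
    values = df.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        bad = np.argwhere(~np.vectorize(np.isreal)(values))
        g, s = bad[0]
        raise FormatError(
            f"{path}: non-numeric count for gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}"
        )
    if values.size:
        frac = values != np.floor(values)
        neg = values < 0
        if frac.any() or neg.any():
            g, s = np.argwhere(frac | neg)[0]
            raise FormatError(
                f"{path}: count for gene {df.index[g]!r}, sample "
                f"{df.columns[s]!r} is {values[g, s]!r}; counts must be "
                f"non-negative integers"
            )
    counts = df.astype(np.int64)
    if annotation_path is None:
        return counts
    annotation = read_annotation(annotation_path)
    missing = counts.index.difference(annotation.index)
    if len(missing):
        raise FormatError(
            f"{annotation_path}: missing annotation for gene(s): "
            f"{missing.tolist()[:10]}"
        )
    return counts, annotation.loc[counts.index]


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="gene_id")
    ann.index = ann.index.astype(str)
    _check_unique(ann.index, "gene ids", path)
    required = {"gc_fraction", "length_bp"}
    missing = required - set(ann.columns)
    if missing:
        raise FormatError(f"{path}: missing annotation column(s): {sorted(missing)}")
    gc = ann["gc_fraction"].to_numpy(float)
    if ((gc < 0) | (gc > 1)).any():
        raise FormatError(f"{path}: gc_fraction outside [0, 1]")
    if (ann["length_bp"].to_numpy(float) <= 0).any():
        raise FormatError(f"{path}: non-positive gene length")
    return ann


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample_id")
    meta.index = meta.index.astype(str)
    _check_unique(meta.index, "sample ids", path)
    for col in ("subject_id", "group"):
        if col not in meta.columns:
            raise FormatError(f"{path}: missing metadata column {col!r}")
    bad = set(meta["group"]) - set(GROUP_LABELS)
    if bad:
        raise FormatError(
            f"{path}: unknown group label(s) {sorted(bad)}; expected {GROUP_LABELS}"
        )
    return meta


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Real-valued matrices (normalized expression, offsets, NPX)
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(df.index, "row ids", path)
    _check_unique(df.columns, "column ids", path)
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path: str | Path, sep: str = "\t",
                 index_label: str = "gene_id") -> None:
    df.to_csv(path, sep=sep, index_label=index_label)


def read_npx(path: str | Path) -> pd.DataFrame:
    """Read an NPX (log2-scale) protein x sample CSV matrix."""
    npx = read_matrix(path, sep=",")
    if not np.isfinite(npx.to_numpy()).all():
        raise FormatError(f"{path}: NPX matrix contains non-finite values")
    return npx


def write_npx(npx: pd.DataFrame, path: str | Path) -> None:
    write_matrix(npx, path, sep=",", index_label="protein_id")


def read_serum(path: str | Path) -> pd.DataFrame:
    """Read a long-form serum marker table (subject_id, marker, timepoint, value)."""
    df = pd.read_csv(path)
    required = {"subject_id", "marker", "timepoint", "value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing serum column(s): {sorted(missing)}")
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def write_serum(serum: pd.DataFrame, path: str | Path) -> None:
    serum.to_csv(path, index=False)


def read_qpcr(path: str | Path) -> pd.DataFrame:
    """Read a long-form qPCR table (gene, participant, cell_type, ct)."""
    df = pd.read_csv(path)
    required = {"gene", "participant", "cell_type", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing qPCR column(s): {sorted(missing)}")
    ct = df["ct"].to_numpy(float)
    ok = np.isnan(ct) | ((ct > 0) & (ct < 45))
    if not ok.all():
        raise FormatError(f"{path}: Ct values must lie in (0, 45)")
    return df


def write_qpcr(qpcr: pd.DataFrame, path: str | Path) -> None:
    qpcr.to_csv(path, index=False)


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# YAML run configuration
# ---------------------------------------------------------------------------

#: Allowed keys per config section; unknown keys are rejected to catch typos.
CONFIG_SCHEMA: dict[str, set[str]] = {
    "simulate": {
        "n_placebo", "n_treated", "n_genes", "set_size_oc", "set_size_ob",
        "n_secreted", "secreted_in_oc", "coupling_loading", "suppression_log2fc",
        "coupled_ob_fraction", "dispersion", "lib_size_range", "gc_effect",
        "marker_noise_sd", "seed",
    },
    "normalize": {"counts", "annotation", "fit_on_filtered", "metadata"},
    "de": {"counts", "annotation", "metadata", "alpha", "fdr_threshold",
           "prior_weight"},
    "coupling": {"normalized", "gene_sets", "metadata", "set_a", "set_b",
                 "subjects", "n_perm", "seed", "measures"},
    "triage": {"de_centrifuged", "de_osteocyte", "detected_osteocyte",
               "gene_sets", "secreted_set", "qpcr", "alpha", "n_keep"},
    "biomarkers": {"serum", "npx", "metadata", "baseline_timepoint",
                   "followup_timepoint", "pairs"},
}


class ConfigError(ValueError):
    """A YAML run configuration is invalid."""


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML run configuration.

    The file holds one top-level mapping per subcommand; unknown sections or
    keys raise :class:`ConfigError` so that typos fail loudly.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping of sections")
    for section, body in cfg.items():
        if section not in CONFIG_SCHEMA:
            raise ConfigError(
                f"{path}: unknown section {section!r}; expected one of "
                f"{sorted(CONFIG_SCHEMA)}"
            )
        body = body or {}
        if not isinstance(body, dict):
            raise ConfigError(f"{path}: section {section!r} must be a mapping")
        unknown = set(body) - CONFIG_SCHEMA[section]
        if unknown:
            raise ConfigError(
                f"{path}: section {section!r}: unknown key(s) {sorted(unknown)}"
            )
    return cfg
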