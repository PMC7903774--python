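"""Fold-change quantification and cross-layer identifier matching.

The analysis consumes per-gene log2 fold changes (transgenic relative to
wild type) in up to four omics layers: a synaptosomal ``proteome`` and three
transcriptome layers (``whole_tissue``, ``syn_input``, ``syn_polysome``).
This module computes fold changes from replicate count matrices, normalizes
gene identifiers, and joins the layers into a matched-profile table keyed on
the proteome — the proteome is the standard: every proteome identifier gets
a row, and transcript values are recorded as missing (never imputed) where a
layer lacks the gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, InputError

logger = logging.getLogger(__name__)

#: Canonical layer names, proteome last.
TRANSCRIPT_LAYERS = ("whole_tissue", "syn_input", "syn_polysome")
LAYERS = TRANSCRIPT_LAYERS + ("proteome",)

#: Column name for the protein fold change in a matched-profile table.
PROTEIN_COLUMN = "protein_log2fc"

DUPLICATE_POLICIES = ("max_abs", "mean", "error")


def normalize_identifier(raw: str) -> str:
    """Canonicalize a gene symbol: strip surrounding whitespace and casefold.

    All joins across layers use this form, so ``"SHANK3"``, ``"Shank3"`` and
    ``"Shank3 "`` all match.

    Raises
    ------
    InputError
        If the input is empty or whitespace-only.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise InputError(f"empty or whitespace-only identifier: {raw!r}")
    return raw.strip().casefold()


def normalize_identifiers(raw: Iterable[str]) -> list[str]:
    """Vector form of :func:`normalize_identifier` (order preserved)."""
    return [normalize_identifier(r) for r in raw]


@dataclass
class FoldChangeTable:
    """Per-gene signed log2 fold change for one omics layer.

    ``values`` is a pandas Series indexed by normalized identifier. The
    index may contain duplicates straight after loading; they are resolved
    by :func:`match_layers` (or :meth:`resolve_duplicates`) according to a
    duplicate policy.
    """

    layer: str
    values: pd.Series

    def __post_init__(self) -> None:
        s = pd.Series(self.values, dtype=float)
        s.index = pd.Index(normalize_identifiers(s.index), name="id")
        s.name = "log2fc"
        if not np.isfinite(s.to_numpy()).all():
            bad = s.index[~np.isfinite(s.to_numpy())].tolist()
            raise InputError(
                f"non-finite fold change in layer {self.layer!r} for: {bad[:5]}"
            )
        self.values = s

    def __len__(self) -> int:
        return len(self.values)

    @property
    def has_duplicates(self) -> bool:
        return bool(self.values.index.has_duplicates)

    def resolve_duplicates(self, policy: str = "max_abs") -> "FoldChangeTable":
        """Collapse duplicate identifiers.

        ``max_abs`` keeps the entry with the largest absolute fold change
        (ties broken by first occurrence); ``mean`` averages; ``error``
        raises :class:`DataError` listing the offenders.
        """
        if policy not in DUPLICATE_POLICIES:
            raise InputError(f"unknown duplicate_policy {policy!r}")
        if not self.has_duplicates:
            return self
        dupes = sorted(set(self.values.index[self.values.index.duplicated()]))
        if policy == "error":
            raise DataError(
                f"duplicate identifiers in layer {self.layer!r}: {dupes}"
            )
        logger.warning(
            "layer %s: collapsing %d duplicated identifier(s) with policy %s",
            self.layer, len(dupes), policy,
        )
        if policy == "mean":
            resolved = self.values.groupby(level=0, sort=False).mean()
        else:  # max_abs, stable: first occurrence wins ties
            frame = self.values.reset_index()
            frame["absfc"] = frame["log2fc"].abs()
            idx = frame.groupby("id", sort=False)["absfc"].idxmax()
            resolved = frame.loc[idx].set_index("id")["log2fc"]
        out = FoldChangeTable.__new__(FoldChangeTable)
        out.layer = self.layer
        out.values = resolved
        return out

    @classmethod
    def from_mapping(cls, layer: str, entries: Mapping[str, float]) -> "FoldChangeTable":
        return cls(layer=layer, values=pd.Series(dict(entries), dtype=float))

    @classmethod
    def from_tsv(cls, path: str | Path, layer: str | None = None) -> "FoldChangeTable":
        """Read a two-column TSV ``id<TAB>log2fc`` (header required)."""
        path = Path(path)
        frame = pd.read_csv(path, sep="\t", dtype={0: str})
        if frame.shape[1] < 2:
            raise InputError(f"{path}: expected columns id<TAB>log2fc")
        ids = frame.iloc[:, 0]
        try:
            vals = frame.iloc[:, 1].astype(float)
        except (TypeError, ValueError) as exc:
            raise InputError(f"{path}: non-numeric fold change ({exc})") from exc
        if layer is None:
            layer = path.stem
        return cls(layer=layer, values=pd.Series(vals.to_numpy(), index=ids))

    def to_tsv(self, path: str | Path) -> None:
        frame = self.values.rename("log2fc").rename_axis("id").reset_index()
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class MatchReport:
    """Per-layer join bookkeeping from :func:`match_layers`."""

    n_proteins: int
    matched: dict[str, int] = field(default_factory=dict)
    unmatched: dict[str, int] = field(default_factory=dict)
    duplicates_collapsed: dict[str, int] = field(default_factory=dict)

    def to_lines(self) -> list[str]:
        lines = [f"proteome identifiers: {self.n_proteins}"]
        for layer in self.matched:
            lines.append(
                f"layer {layer}: matched={self.matched[layer]} "
                f"unmatched={self.unmatched[layer]} "
                f"duplicates_collapsed={self.duplicates_collapsed.get(layer, 0)}"
            )
        return lines


def compute_log2fc(
    counts: pd.DataFrame,
    genotype_labels: Sequence[str] | None = None,
    pseudocount: float = 1.0,
    normalization: str = "library_size",
) -> FoldChangeTable:
    """Per-gene log2((mean TG + pseudocount) / (mean WT + pseudocount)).

    Parameters
    ----------
    counts
        Gene-by-sample nonnegative count matrix, genes on the index.
    genotype_labels
        One label per column, each ``"WT"`` or ``"TG"`` (case-insensitive).
        If omitted, the genotype is parsed from the column-name prefix
        before the first underscore (the fixture convention
        ``<genotype>_<layer>_<replicate>``).
    pseudocount
        Nonnegative stabilizer added to both genotype means.
    normalization
        ``"library_size"`` scales each column to the mean library size
        before averaging; ``"none"`` uses raw counts.
    """
    if pseudocount < 0:
        raise InputError(f"pseudocount must be nonnegative, got {pseudocount}")
    if normalization not in ("library_size", "none"):
        raise InputError(f"unknown normalization {normalization!r}")
    mat = counts.astype(float)
    if (mat.to_numpy() < 0).any():
        raise InputError("negative counts are not allowed")
    if genotype_labels is None:
        genotype_labels = [str(c).split("_", 1)[0] for c in mat.columns]
    labels = [str(g).upper() for g in genotype_labels]
    if len(labels) != mat.shape[1]:
        raise InputError(
            f"{len(labels)} genotype labels for {mat.shape[1]} columns"
        )
    unknown = sorted(set(labels) - {"WT", "TG"})
    if unknown:
        raise InputError(f"genotype labels must be WT or TG, got {unknown}")
    wt_cols = [c for c, g in zip(mat.columns, labels) if g == "WT"]
    tg_cols = [c for c, g in zip(mat.columns, labels) if g == "TG"]
    for geno, cols in (("WT", wt_cols), ("TG", tg_cols)):
        if not cols:
            raise InputError(f"genotype {geno} has zero replicates")

    if normalization == "library_size":
        lib = mat.sum(axis=0)
        if (lib <= 0).any():
            raise InputError("a column has zero total counts; cannot normalize")
        mat = mat * (lib.mean() / lib)

    wt_mean = mat[wt_cols].mean(axis=1)
    tg_mean = mat[tg_cols].mean(axis=1)
    if pseudocount == 0 and ((wt_mean == 0) | (tg_mean == 0)).any():
        raise InputError(
            "zero genotype mean with pseudocount=0 makes log2fc undefined"
        )
    fc = np.log2(tg_mean + pseudocount) - np.log2(wt_mean + pseudocount)
    return FoldChangeTable(layer="computed", values=pd.Series(fc.to_numpy(), index=mat.index))


def apply_remap(table: FoldChangeTable, remap: Mapping[str, str]) -> FoldChangeTable:
    """Rename identifiers via a raw-id → gene-symbol map (both sides normalized)."""
    mapping = {
        normalize_identifier(k): normalize_identifier(v) for k, v in remap.items()
    }
    renamed = table.values.copy()
    renamed.index = pd.Index(
        [mapping.get(i, i) for i in renamed.index], name="id"
    )
    return FoldChangeTable(layer=table.layer, values=renamed)


def match_layers(
    proteome: FoldChangeTable,
    transcriptomes: Sequence[FoldChangeTable],
    duplicate_policy: str = "max_abs",
) -> tuple[pd.DataFrame, MatchReport]:
    """Join transcript fold changes onto the proteome.

    Returns a matched-profile DataFrame with exactly one row per proteome
    identifier (column ``protein_log2fc``) and one column per transcript
    layer, NaN where the layer lacks the gene, plus a :class:`MatchReport`
    with matched/unmatched counts per layer.
    """
    if len(proteome) == 0:
        raise InputError("proteome table is empty")
    layer_names = [t.layer for t in transcriptomes]
    if len(set(layer_names)) != len(layer_names):
        raise InputError(f"transcriptome layer names not distinct: {layer_names}")
    if "proteome" in layer_names or PROTEIN_COLUMN in layer_names:
        # allowed, but must not collide with the protein column
        if PROTEIN_COLUMN in layer_names:
            raise InputError(f"layer name {PROTEIN_COLUMN!r} is reserved")

    report = MatchReport(n_proteins=0)
    prot = proteome.resolve_duplicates(duplicate_policy)
    if proteome.has_duplicates:
        report.duplicates_collapsed["proteome"] = len(proteome) - len(prot)
    profiles = prot.values.rename(PROTEIN_COLUMN).to_frame()
    report.n_proteins = len(profiles)

    for table in transcriptomes:
        n_raw = len(table)
        resolved = table.resolve_duplicates(duplicate_policy)
        report.duplicates_collapsed[table.layer] = n_raw - len(resolved)
        joined = resolved.values.reindex(profiles.index)
        profiles[table.layer] = joined
        n_matched = int(joined.notna().sum())
        report.matched[table.layer] = n_matched
        report.unmatched[table.layer] = len(profiles) - n_matched

    for line in report.to_lines():
        logger.info("match_layers: %s", line)
    return profiles, report


def profiles_to_tsv(profiles: pd.DataFrame, path: str | Path) -> None:
    """Write a matched-profile table; absent values become empty cells."""
    profiles.rename_axis("id").reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.10g", na_rep=""
    )


def profiles_from_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in frame.columns or PROTEIN_COLUMN not in frame.columns:
        raise InputError(
            f"{path}: matched-profile TSV needs 'id' and '{PROTEIN_COLUMN}' columns"
        )
    frame["id"] = normalize_identifiers(frame["id"])
    frame = frame.set_index("id")
    return frame.astype(float)
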