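"""Readers and writers for the TSV/GMT dialects the pipeline touches.

All tabular files are UTF-8, tab-separated, '.' decimal. Lines starting
with '#' are treated as comment headers and skipped on read; writers emit
a '#' block recording provenance (parameters, seed) above the header row.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    BinaryAlterationMatrix,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    Group,
    GroupAssignment,
    MethylationMatrix,
    MStage,
    NStage,
    Policy,
    ProbeGeneMap,
    SampleRecord,
    YesNoUnknown,
)

__all__ = [
    "read_sample_annotations",
    "write_sample_annotations",
    "read_matrix",
    "write_matrix",
    "read_methylation",
    "collapse_probes",
    "read_probe_gene_map",
    "read_gmt",
    "write_gmt",
    "read_table",
    "write_table",
    "read_group_assignments",
    "write_group_assignments",
]

_N_TOKENS = {"N0": NStage.N0, "N+": NStage.N_PLUS}
_M_TOKENS = {"M0": MStage.M0, "M+": MStage.M_PLUS}
_YN_TOKENS = {"yes": YesNoUnknown.YES, "no": YesNoUnknown.NO}

ANNOTATION_COLUMNS = [
    "sample_id",
    "n_stage",
    "m_stage",
    "recurrence",
    "adjuvant",
    "follow_up_months",
]


def _is_missing(tok: str) -> bool:
    return tok.strip() in ("", "NA")


def _rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment lines."""
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].startswith("#")):
                continue
            yield lineno, row


def read_sample_annotations(path: str | Path) -> list[SampleRecord]:
    """Read per-sample staging/recurrence/treatment annotations.

    Tokens: N0/N+, M0/M+, yes/no; an empty cell or "NA" maps to
    unknown/missing. Duplicate sample ids and unrecognized tokens are hard
    errors (naming the offending id / row).
    """
    it = iter(_rows(path))
    try:
        _, header = next(it)
    except StopIteration:
        raise ValueError(f"{path}: empty annotation file") from None
    if [h.strip() for h in header] != ANNOTATION_COLUMNS:
        raise ValueError(
            f"{path}: expected header {ANNOTATION_COLUMNS}, got {header}"
        )
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for lineno, row in it:
        if len(row) != len(ANNOTATION_COLUMNS):
            raise ValueError(
                f"{path}:{lineno}: expected {len(ANNOTATION_COLUMNS)} fields, "
                f"got {len(row)}"
            )
        sid, n_tok, m_tok, rec_tok, adj_tok, fu_tok = (f.strip() for f in row)
        if sid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate sample_id {sid!r}")
        seen.add(sid)

        def _enum(tok: str, table: Mapping[str, object], unknown, col: str):
            if _is_missing(tok):
                return unknown
            try:
                return table[tok]
            except KeyError:
                raise ValueError(
                    f"{path}:{lineno}: unrecognized {col} token {tok!r}"
                ) from None

        n_stage = _enum(n_tok, _N_TOKENS, NStage.UNKNOWN, "n_stage")
        m_stage = _enum(m_tok, _M_TOKENS, MStage.UNKNOWN, "m_stage")
        recurrence = _enum(rec_tok, _YN_TOKENS, YesNoUnknown.UNKNOWN, "recurrence")
        adjuvant = _enum(adj_tok, _YN_TOKENS, YesNoUnknown.UNKNOWN, "adjuvant")
        if _is_missing(fu_tok):
            follow_up = None
        else:
            try:
                follow_up = float(fu_tok)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric follow_up_months {fu_tok!r}"
                ) from None
        records.append(
            SampleRecord(sid, n_stage, m_stage, recurrence, adjuvant, follow_up)
        )
    return records


def write_sample_annotations(
    records: Sequence[SampleRecord], path: str | Path, comments: Sequence[str] = ()
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for r in records:
            fu = "" if r.follow_up_months is None else repr(float(r.follow_up_months))
            tok = lambda e: "" if e.value == "unknown" else e.value
            fh.write(
                "\t".join(
                    [
                        r.sample_id,
                        tok(r.n_stage),
                        tok(r.m_stage),
                        tok(r.recurrence),
                        tok(r.adjuvant),
                        fu,
                    ]
                )
                + "\n"
            )


def _read_numeric_frame(path: str | Path, allow_na: bool = False) -> pd.DataFrame:
    """Strictly parse a feature-by-sample TSV matrix."""
    it = iter(_rows(path))
    try:
        _, header = next(it)
    except StopIteration:
        raise ValueError(f"{path}: no features (empty file)") from None
    sample_ids = [h.strip() for h in header[1:]]
    if not sample_ids:
        raise ValueError(f"{path}: header has no sample columns")
    n_fields = len(header)
    feature_ids: list[str] = []
    data: list[list[float]] = []
    for lineno, row in it:
        if len(row) != n_fields:
            raise ValueError(
                f"{path}:{lineno}: ragged row ({len(row)} fields, "
                f"expected {n_fields})"
            )
        feature_ids.append(row[0].strip())
        vals: list[float] = []
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if allow_na and _is_missing(cell):
                vals.append(np.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric cell {cell!r} at feature "
                    f"{row[0]!r}, sample {sample_ids[j]!r}"
                ) from None
        data.append(vals)
    if not feature_ids:
        raise ValueError(f"{path}: no features")
    return pd.DataFrame(data, index=feature_ids, columns=sample_ids, dtype=float)


def read_matrix(path: str | Path, scale: str) -> ExpressionMatrix:
    """Read an expression TSV (first column feature ids, header = sample ids).

    ``scale="raw_count"`` additionally enforces non-negative integers; the
    offending coordinate is named on failure.
    """
    df = _read_numeric_frame(path)
    if scale == "raw_count":
        arr = df.to_numpy()
        bad = ~np.isclose(arr, np.round(arr)) | (arr < 0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"{path}: raw_count matrix has invalid value {arr[i, j]!r} at "
                f"feature {df.index[i]!r}, sample {df.columns[j]!r}"
            )
        df = df.round().astype(np.int64).astype(float)
    return ExpressionMatrix(df, scale)


def write_matrix(
    m: ExpressionMatrix | pd.DataFrame,
    path: str | Path,
    comments: Sequence[str] = (),
    index_label: str = "feature_id",
) -> None:
    df = m.values if isinstance(m, ExpressionMatrix) else m
    with open(path, "w", encoding="utf-8") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index_label=index_label, lineterminator="\n")


def read_probe_gene_map(path: str | Path) -> ProbeGeneMap:
    rows = []
    it = iter(_rows(path))
    try:
        _, header = next(it)
    except StopIteration:
        raise ValueError(f"{path}: empty probe-gene map") from None
    if [h.strip() for h in header[:2]] != ["probe_id", "gene_id"]:
        raise ValueError(f"{path}: expected header probe_id<TAB>gene_id")
    for lineno, row in it:
        if len(row) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 fields")
        rows.append((row[0].strip(), row[1].strip()))
    return ProbeGeneMap(pd.DataFrame(rows, columns=["probe_id", "gene_id"]))


def read_methylation(
    beta_path: str | Path, promoter_map_path: str | Path
) -> tuple[MethylationMatrix, dict]:
    """Read a beta-value matrix plus its locus-to-promoter-gene map.

    Loci with any missing beta value are dropped cohort-wide; the second
    return value is a load report with the counts.
    """
    df = _read_numeric_frame(beta_path, allow_na=True)
    incomplete = df.isna().any(axis=1)
    report = {
        "n_loci_input": int(df.shape[0]),
        "n_loci_dropped_missing": int(incomplete.sum()),
        "n_loci_kept": int((~incomplete).sum()),
    }
    df = df.loc[~incomplete]
    pmap = read_probe_gene_map(promoter_map_path).pairs.rename(
        columns={"probe_id": "locus_id"}
    )
    return MethylationMatrix(df, pmap), report


def collapse_probes(
    m: ExpressionMatrix, pmap: ProbeGeneMap
) -> tuple[ExpressionMatrix, dict]:
    """Collapse probe-level log2 intensities to gene level.

    Each gene's row is the arithmetic mean, on the stored log2 scale, of
    all probes mapped to it; a probe mapped to several genes contributes
    to every one of them. Probes absent from the map are dropped and
    counted in the returned report.
    """
    if m.scale != "log2_intensity":
        raise ValueError("collapse_probes requires a log2_intensity matrix")
    mapped = pmap.pairs[pmap.pairs["probe_id"].isin(m.values.index)]
    unmapped = set(m.values.index) - set(mapped["probe_id"])
    expanded = m.values.loc[mapped["probe_id"]].set_index(
        mapped["gene_id"].to_numpy()
    )
    collapsed = expanded.groupby(level=0, sort=True).mean()
    collapsed.index.name = m.values.index.name
    report = {
        "n_probes_input": int(m.values.shape[0]),
        "n_probes_unmapped_dropped": len(unmapped),
        "n_genes_output": int(collapsed.shape[0]),
    }
    return ExpressionMatrix(collapsed, "log2_intensity"), report


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT v2 gene-set file (set_id TAB description TAB member...)."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3"
                )
            set_id = fields[0].strip()
            if set_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicated set_id {set_id!r}")
            seen.add(set_id)
            members = tuple(g.strip() for g in fields[2:] if g.strip())
            sets.append(GeneSet(set_id, fields[1].strip(), members))
    return GeneSetCollection.from_sets(sets)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in coll:
            fh.write("\t".join([s.set_id, s.description, *s.members]) + "\n")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a generic TSV result table ('#' comment lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    comments: Sequence[str] = (),
    index: bool = False,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def write_group_assignments(
    assignments: Sequence[GroupAssignment],
    path: str | Path,
    comments: Sequence[str] = (),
) -> None:
    df = pd.DataFrame(
        [
            (a.sample_id, a.group.value, a.policy.value, a.reason)
            for a in assignments
        ],
        columns=["sample_id", "group", "policy", "reason"],
    )
    write_table(df, path, comments)


def read_group_assignments(path: str | Path) -> list[GroupAssignment]:
    df = read_table(path)
    return [
        GroupAssignment(
            str(r.sample_id), Group(r.group), Policy(r.policy), str(r.reason)
        )
        for r in df.itertuples(index=False)
    ]
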