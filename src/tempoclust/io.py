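"""Reading and writing the pipeline's on-disk formats.

Matrices and result tables travel as TSV with gene/sample identifiers
(never positions); annotation terms as standard GMT; dendrograms as
newick.  Profile matrices carry a ``#`` header comment recording the
view, strains and times so a file is self-describing.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, ProfileMatrix
from .enrichment import TermMap
from .integrate import StudyComparison


def write_expression_tsv(ds: ExpressionDataset, path, metadata_path) -> None:
    ds.values.to_csv(path, sep="\t", index_label="gene")
    meta = ds.metadata.loc[ds.samples]
    meta.to_csv(metadata_path, sep="\t", index_label="sample")


def read_expression_tsv(path, metadata_path) -> ExpressionDataset:
    """Read a gene x sample TSV plus its sample-metadata TSV.

    Rejects ragged rows, non-numeric cells and duplicate gene ids with
    the offending line number or identifier; every sample column must be
    covered by the metadata.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_fields = len(header)
        rows, genes = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_fields:
                raise ValueError(
                    f"{path.name}:{lineno}: expected {n_fields} fields, got {len(fields)}"
                )
            genes.append(fields[0])
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError as err:
                raise ValueError(f"{path.name}:{lineno}: non-numeric cell ({err})") from None
    samples = header[1:]
    seen: set[str] = set()
    for g in genes:
        if g in seen:
            raise ValueError(f"duplicate gene id {g!r} in {path.name}")
        seen.add(g)
    values = pd.DataFrame(np.asarray(rows, dtype=float), index=genes, columns=samples)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col="sample")
    missing = [s for s in samples if s not in metadata.index]
    if missing:
        raise ValueError(f"metadata missing sample(s): {missing[:5]}")
    return ExpressionDataset(values=values, metadata=metadata)


def write_profile_tsv(pm: ProfileMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# view={pm.view}\tstrains={','.join(map(str, pm.strain_context))}"
            f"\ttimes={','.join(map(str, pm.times))}"
            f"\tdegenerate={','.join(pm.degenerate)}\n"
        )
        pm.values.to_csv(fh, sep="\t", index_label="gene")


def read_profile_tsv(path) -> ProfileMatrix:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("profile TSV must start with a '# view=...' comment line")
        fields = dict(f.split("=", 1) for f in header[1:].strip().split("\t"))
        values = pd.read_csv(fh, sep="\t", index_col="gene")
    times = [float(t) for t in fields["times"].split(",") if t]
    degenerate = [g for g in fields.get("degenerate", "").split(",") if g]
    return ProfileMatrix(
        values=values, view=fields["view"], times=times,
        strain_context=tuple(fields["strains"].split(",")), degenerate=degenerate,
    )


def read_gmt(path) -> TermMap:
    """Parse a GMT file: term, description, then >= 1 tab-separated genes."""
    path = Path(path)
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: GMT line needs term, description and >= 1 gene"
                )
            term = fields[0]
            if term in terms:
                raise ValueError(f"{path.name}:{lineno}: duplicate term id {term!r}")
            terms[term] = {g for g in fields[2:] if g}
    universe = set().union(*terms.values()) if terms else set()
    return TermMap(terms=terms, universe=universe)


def write_gmt(termmap: TermMap, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for term, genes in termmap.terms.items():
            fh.write("\t".join([term, description, *sorted(genes)]) + "\n")


def read_study_tsv(path, study_id: str | None = None, note: str = "") -> StudyComparison:
    """Read one study's (gene, log2_ratio, significant) TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "log2_ratio", "significant"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path.name}: expected columns {sorted(required)}")
    return StudyComparison(
        study_id=study_id or path.stem,
        ratios=pd.Series(df["log2_ratio"].to_numpy(), index=df["gene"]),
        significant=pd.Series(df["significant"].astype(bool).to_numpy(), index=df["gene"]),
        note=note,
    )


def write_study_tsv(study: StudyComparison, path) -> None:
    pd.DataFrame({
        "gene": study.ratios.index,
        "log2_ratio": study.ratios.to_numpy(),
        "significant": study.significant.astype(int).to_numpy(),
    }).to_csv(path, sep="\t", index=False)


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping, for output provenance headers."""
    canon = repr(sorted(config.items())) if isinstance(config, dict) else repr(config)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, comment: str | None = None, index=False,
                index_label=None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)
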