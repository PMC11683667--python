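"""Readers and writers for the on-disk formats the pipeline exchanges.

Expression matrices travel as Matrix-Market coordinate files plus one-column
gene/barcode label files (the 10x triplet convention); gene sets as GMT; cell
metadata, variant calls, gene→chromosome-arm maps and survival tables as TSV;
run configuration as flat JSON.  Matrix-Market indices are 1-based on disk and
0-based in memory — the conversion happens only here.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import FormatError, ParameterError

RAW_COUNTS = "raw_counts"
LOG_NORMALIZED = "log_normalized"

VARIANT_COLUMNS = ["cell_id", "gene", "variant_id", "protein_change", "in_cosmic", "dbsnp_freq"]


@dataclass
class ExpressionMatrix:
    """Genes × observations expression values with aligned labels.

    ``mode`` is ``raw_counts`` for integer count data and ``log_normalized``
    after library-size normalisation; every downstream operation states which
    mode it expects.
    """

    values: np.ndarray
    gene_ids: list[str]
    obs_ids: list[str]
    mode: str = RAW_COUNTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.obs_ids = list(self.obs_ids)
        if self.values.ndim != 2:
            raise ParameterError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.obs_ids)):
            raise ParameterError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.obs_ids)} observations"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ParameterError("duplicate gene identifiers")
        if len(set(self.obs_ids)) != len(self.obs_ids):
            raise ParameterError("duplicate observation identifiers")
        if self.mode == RAW_COUNTS:
            if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
                raise ParameterError("raw counts must be finite and non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present in matrix") from None

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene), :]

    def subset(self, gene_mask=None, obs_mask=None) -> "ExpressionMatrix":
        """Return a copy restricted to masked genes/observations, order preserved."""
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        om = np.ones(self.n_obs, bool) if obs_mask is None else np.asarray(obs_mask)
        if gm.dtype != bool:
            idx = np.zeros(self.n_genes, bool)
            idx[gm] = True
            gm = idx
        if om.dtype != bool:
            idx = np.zeros(self.n_obs, bool)
            idx[om] = True
            om = idx
        return ExpressionMatrix(
            self.values[np.ix_(gm, om)],
            [g for g, k in zip(self.gene_ids, gm) if k],
            [o for o, k in zip(self.obs_ids, om) if k],
            mode=self.mode,
        )


@dataclass
class GeneSet:
    name: str
    genes: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ParameterError(f"gene set {self.name!r} is empty")
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g, None)
        self.genes = list(seen)


class GeneSetCollection:
    """Ordered, name-unique collection of gene sets (GMT round-trippable)."""

    def __init__(self, sets: Iterable[GeneSet] = ()) -> None:
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            self.add(s)

    def add(self, s: GeneSet) -> None:
        if s.name in self._sets:
            raise ParameterError(f"duplicate gene set name {s.name!r}")
        self._sets[s.name] = s

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)


def _read_labels(path: str | Path) -> list[str]:
    labels = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                labels.append(line.split("\t")[0])
    return labels


def _dedupe_genes(genes: list[str]) -> list[str]:
    # duplicate symbols get an ordinal suffix so labels stay unique
    seen: dict[str, int] = {}
    out = []
    for g in genes:
        n = seen.get(g, 0)
        out.append(g if n == 0 else f"{g}.{n}")
        seen[g] = n + 1
    return out


def read_counts(path_matrix: str | Path, path_genes: str | Path, path_obs: str | Path) -> ExpressionMatrix:
    """Read a Matrix-Market counts triplet into a raw-count ExpressionMatrix."""
    try:
        mat = scipy.io.mmread(str(path_matrix))
    except Exception as exc:  # pragma: no cover - scipy message passthrough
        raise FormatError(f"cannot parse Matrix-Market file {path_matrix}: {exc}") from exc
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    genes = _read_labels(path_genes)
    obs = _read_labels(path_obs)
    if dense.shape[0] != len(genes):
        raise FormatError(
            f"gene label file {path_genes} has {len(genes)} entries but matrix has {dense.shape[0]} rows"
        )
    if dense.shape[1] != len(obs):
        raise FormatError(
            f"observation label file {path_obs} has {len(obs)} entries but matrix has {dense.shape[1]} columns"
        )
    return ExpressionMatrix(dense, _dedupe_genes(genes), obs, mode=RAW_COUNTS)


def write_counts(expr: ExpressionMatrix, path_matrix: str | Path, path_genes: str | Path, path_obs: str | Path) -> None:
    scipy.io.mmwrite(str(path_matrix), scipy.sparse.coo_matrix(expr.values))
    Path(path_genes).write_text("".join(g + "\n" for g in expr.gene_ids))
    Path(path_obs).write_text("".join(o + "\n" for o in expr.obs_ids))


def read_gmt(path: str | Path) -> GeneSetCollection:
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
            coll.add(GeneSet(name=fields[0], description=fields[1], genes=[g for g in fields[2:] if g]))
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in coll:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a per-cell variant-call table (TSV).

    ``dbsnp_freq`` may be NA, meaning the variant is unobserved in the
    population database; downstream rarity filters treat NA as passing.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "gene": str, "variant_id": str, "protein_change": str})
    for col in VARIANT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"variant table {path} is missing required column {col!r}")
    df = df[VARIANT_COLUMNS].copy()
    df["in_cosmic"] = df["in_cosmic"].astype(int)
    df["dbsnp_freq"] = pd.to_numeric(df["dbsnp_freq"], errors="coerce")
    bad = df["dbsnp_freq"].dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise FormatError(f"variant table {path}: dbsnp_freq outside [0, 1]")
    return df


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    df[VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_arm_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene", "chrom", "arm"):
        if col not in df.columns:
            raise FormatError(f"gene-arm table {path} is missing required column {col!r}")
    return df


def read_survival_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise FormatError(f"survival table {path} is missing required column {col!r}")
    if (df["time"] < 0).any():
        raise FormatError(f"survival table {path}: negative times")
    if not set(df["event"].unique()) <= {0, 1}:
        raise FormatError(f"survival table {path}: event must be 0/1")
    return df


@dataclass
class RunConfig:
    """Flat, JSON-serialisable run configuration with one global seed.

    Per-stage random streams are derived deterministically from the global
    seed and the stage name, so stages can be re-run in isolation.
    """

    seed: int = 0
    outdir: str = "gliosig_run"
    species: str = "mouse"
    params: dict = field(default_factory=dict)

    def stage_seed(self, stage: str) -> int:
        import zlib

        return int((int(self.seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        if not isinstance(data, Mapping):
            raise FormatError(f"config {path} is not a JSON object")
        return cls(**data)
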