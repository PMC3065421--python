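"""Shared data model, tabular I/O and normalization for two-color calibration data.

The central container is :class:`ExpressionSet`: a genes x channel-observations
matrix of (log-like) intensities with per-observation metadata describing the
two-color dye-swap design (slide, dye, binary sample label, protocol label).
A valid set is balanced: every slide carries exactly two observations with
opposite dyes and opposite sample labels, so each slide compares the same two
biological samples with reversed labelling on half the slides.

Files are plain TSV with metadata header lines (``#slide``, ``#dye``,
``#sample``, optional ``#protocol`` and ``#transform``), one column per
channel-observation and one row per gene.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ExpressionSet",
    "AnnotationTable",
    "Config",
    "FormatError",
    "ValidationError",
    "read_expression_table",
    "write_expression_table",
    "normalize",
    "read_annotation",
]

TRANSFORMS = ("raw", "log2", "normalized")
DYES = ("Cy3", "Cy5")
OBS_COLUMNS = ("slide", "dye", "sample", "protocol")


class FormatError(ValueError):
    """Raised when an input file does not match the expected table layout."""


class ValidationError(ValueError):
    """Raised when data violates an invariant of the experimental design."""


@dataclass
class ExpressionSet:
    """Expression matrix (G genes x N channel-observations) plus design metadata.

    Parameters
    ----------
    gene_ids:
        Unique gene/probe identifiers, one per row of ``values``.
    values:
        Real intensity matrix, shape ``(G, N)``, no missing entries.
    obs:
        Per-observation metadata frame with columns ``slide``, ``dye``
        (``Cy3``/``Cy5``), ``sample`` (binary label, 0/1) and ``protocol``
        (free-form string such as ``"51C"``).
    transform:
        One of ``raw``, ``log2``, ``normalized`` recording the scale of
        ``values``.
    """

    gene_ids: list[str]
    values: np.ndarray
    obs: pd.DataFrame
    transform: str = "log2"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.obs = self.obs.reset_index(drop=True).copy()
        if "protocol" not in self.obs.columns:
            self.obs["protocol"] = "NA"
        self.obs["slide"] = self.obs["slide"].astype(str)
        self.obs["dye"] = self.obs["dye"].astype(str)
        self.obs["sample"] = self.obs["sample"].astype(int)
        self.obs["protocol"] = self.obs["protocol"].astype(str)
        self.validate()

    # -- basic attributes -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_obs(self) -> int:
        return self.values.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Binary sample labels as an int array of length N."""
        return self.obs["sample"].to_numpy()

    @property
    def slides(self) -> list[str]:
        """Slide identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.obs["slide"]:
            seen.setdefault(s, None)
        return list(seen)

    def validate(self) -> None:
        """Check all design invariants; raise :class:`ValidationError` otherwise."""
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        g, n = self.values.shape
        if g < 1:
            raise ValidationError("at least one gene is required")
        if n < 4:
            raise ValidationError(f"at least 4 observations required, got {n}")
        if len(self.gene_ids) != g:
            raise ValidationError("gene_ids length does not match values rows")
        if len(set(self.gene_ids)) != g:
            raise ValidationError("gene ids must be unique")
        if len(self.obs) != n:
            raise ValidationError("obs metadata length does not match values columns")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values contain missing or non-finite entries")
        if self.transform not in TRANSFORMS:
            raise ValidationError(f"unknown transform {self.transform!r}")
        bad_dye = set(self.obs["dye"]) - set(DYES)
        if bad_dye:
            raise ValidationError(f"unknown dye labels: {sorted(bad_dye)}")
        bad_y = set(self.obs["sample"]) - {0, 1}
        if bad_y:
            raise ValidationError(f"sample labels must be 0/1, got {sorted(bad_y)}")
        offending = []
        for slide, grp in self.obs.groupby("slide", sort=False):
            if (
                len(grp) != 2
                or set(grp["sample"]) != {0, 1}
                or set(grp["dye"]) != set(DYES)
            ):
                offending.append(slide)
        if offending:
            raise ValidationError(
                "slides without a complete dye-swap pair (one observation per "
                f"dye with opposite sample labels): {offending}"
            )
        y = self.y
        if y.sum() * 2 != n:
            raise ValidationError("design is not balanced in sample labels")

    # -- convenience ------------------------------------------------------
    def copy(self, **changes) -> "ExpressionSet":
        base = dict(
            gene_ids=list(self.gene_ids),
            values=self.values.copy(),
            obs=self.obs.copy(),
            transform=self.transform,
        )
        base.update(changes)
        return ExpressionSet(**base)

    def subset_genes(self, genes: Sequence[str] | Sequence[int] | np.ndarray) -> "ExpressionSet":
        """Return a new set restricted to ``genes`` (ids or integer indices)."""
        genes = list(genes)
        if len(genes) == 0:
            raise ValidationError("empty gene subset")
        if all(isinstance(g, (int, np.integer)) for g in genes):
            idx = [int(g) for g in genes]
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            missing = [g for g in genes if g not in pos]
            if missing:
                raise ValidationError(f"unknown gene ids in subset: {missing[:5]}")
            idx = [pos[g] for g in genes]
        return ExpressionSet(
            gene_ids=[self.gene_ids[i] for i in idx],
            values=self.values[idx],
            obs=self.obs.copy(),
            transform=self.transform,
        )

    def __eq__(self, other: object) -> bool:  # value equality, used in round-trip tests
        if not isinstance(other, ExpressionSet):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.transform == other.transform
            and np.array_equal(self.values, other.values)
            and self.obs[list(OBS_COLUMNS)].equals(other.obs[list(OBS_COLUMNS)])
        )


@dataclass
class AnnotationTable:
    """gene id -> binary category flag (e.g. is-transcription-factor)."""

    flags: pd.Series  # bool values indexed by gene id
    category: str = "flag"

    def __post_init__(self) -> None:
        if not self.flags.index.is_unique:
            raise ValidationError("annotation gene ids must be unique")
        self.flags = self.flags.astype(bool)

    def __len__(self) -> int:
        return len(self.flags)

    def flag_for(self, gene_ids: Iterable[str]) -> np.ndarray:
        """Boolean flags aligned to ``gene_ids``; genes absent from the table are False."""
        return self.flags.reindex(list(gene_ids), fill_value=False).to_numpy()


@dataclass
class Config:
    """Run configuration with defaults for every tunable of the pipeline."""

    seed: int = 0
    normalization: str = "none"  # none | location | location_scale
    log_floor: float = 1.0  # raw intensities clipped here before log2
    fdr_q: float = 0.01
    sigma_floor: float = 1e-6
    posterior_eps: float = 1e-6
    n_subsamples: int = 100
    subsample_size: int | None = None  # default: G // 4
    folds: int | str = "loo"
    top_share_threshold: float = 0.5
    entropy_threshold_bits: float = 1.5
    adjacency_window_celsius: float = 2.0
    simulator: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_q < 1.0:
            raise ValidationError("fdr_q must lie in (0, 1)")
        if self.normalization not in ("none", "location", "location_scale"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")
        for name in ("n_subsamples",):
            if int(getattr(self, name)) <= 0:
                raise ValidationError(f"{name} must be a positive integer")
        if self.subsample_size is not None and int(self.subsample_size) <= 0:
            raise ValidationError("subsample_size must be a positive integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_META_KEYS = ("slide", "dye", "sample", "protocol", "transform")


def read_expression_table(path: str | Path) -> ExpressionSet:
    """Read an expression TSV with metadata header lines into an ExpressionSet.

    Expected layout: lines ``#slide``/``#dye``/``#sample`` (required) and
    ``#protocol``/``#transform`` (optional), then a header row whose first
    column is the gene-id column, then one row per gene.
    """
    meta: dict[str, list[str]] = {}
    transform = "log2"
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                fields = line[1:].split("\t")
                key = fields[0].strip().lower()
                if key not in _META_KEYS:
                    raise FormatError(f"unknown metadata line #{key}")
                if key == "transform":
                    transform = fields[1].strip()
                else:
                    meta[key] = [f.strip() for f in fields[1:]]
            elif line:
                body_lines.append(line)
    for required in ("slide", "dye", "sample"):
        if required not in meta:
            raise FormatError(f"missing required metadata line #{required}")
    df = pd.read_csv(
        io.StringIO("\n".join(body_lines)),
        sep="\t",
        index_col=0,
        float_precision="round_trip",
    )
    n = df.shape[1]
    for key, vals in meta.items():
        if len(vals) != n:
            raise FormatError(
                f"metadata line #{key} has {len(vals)} entries for {n} data columns"
            )
    obs = pd.DataFrame(
        {
            "slide": meta["slide"],
            "dye": meta["dye"],
            "sample": [int(v) for v in meta["sample"]],
            "protocol": meta.get("protocol", ["NA"] * n),
        }
    )
    return ExpressionSet(
        gene_ids=[str(g) for g in df.index],
        values=df.to_numpy(dtype=float),
        obs=obs,
        transform=transform,
    )


def _canonical_order(obs: pd.DataFrame) -> np.ndarray:
    """Deterministic column order: by slide id, then dye (Cy3 before Cy5)."""
    key = list(zip(obs["slide"], obs["dye"]))
    return np.array(sorted(range(len(key)), key=key.__getitem__), dtype=int)


def write_expression_table(es: ExpressionSet, path: str | Path) -> None:
    """Write ``es`` as TSV; columns sorted by (slide, dye) for reproducibility.

    Values are written with shortest-exact float representation so that a
    write -> read round trip is bit-exact.
    """
    order = _canonical_order(es.obs)
    obs = es.obs.iloc[order]
    values = es.values[:, order]
    with open(path, "w", newline="\n") as fh:
        fh.write(f"#transform\t{es.transform}\n")
        for key in ("slide", "dye", "sample", "protocol"):
            fh.write("#" + key + "\t" + "\t".join(str(v) for v in obs[key]) + "\n")
        col_names = [f"{s}.{d}" for s, d in zip(obs["slide"], obs["dye"])]
        fh.write("gene_id\t" + "\t".join(col_names) + "\n")
        for gid, row in zip(es.gene_ids, values):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize(
    es: ExpressionSet, method: str = "none", log_floor: float = 1.0
) -> ExpressionSet:
    """Per-observation normalization of the log2 signal.

    ``raw`` input is first clipped at ``log_floor`` and log2-transformed.
    ``location`` subtracts each observation column's mean; ``location_scale``
    additionally divides by the column's population (1/n) standard deviation,
    matching the maximum-likelihood conventions used by the model fits.
    """
    if method not in ("none", "location", "location_scale"):
        raise ValueError(f"unknown normalization method {method!r}")
    values = es.values
    if es.transform == "raw":
        values = np.log2(np.maximum(values, log_floor))
    if method == "none":
        return es.copy(values=values, transform="log2" if es.transform == "raw" else es.transform)
    centered = values - values.mean(axis=0, keepdims=True)
    if method == "location_scale":
        sd = values.std(axis=0, ddof=0)
        zero = np.flatnonzero(sd == 0.0)
        if zero.size:
            labels = [
                f"{es.obs['slide'].iloc[i]}.{es.obs['dye'].iloc[i]}" for i in zero
            ]
            raise ValidationError(
                f"zero variance in observation column(s) {labels}; "
                "cannot apply scale normalization"
            )
        centered = centered / sd
    return es.copy(values=centered, transform="normalized")


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

_TRUE = {"1", "true", "yes", "t", "y"}
_FALSE = {"0", "false", "no", "f", "n"}


def _parse_flag(token: str) -> bool | None:
    t = token.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    return None


def read_annotation(path: str | Path) -> AnnotationTable:
    """Read a two-column TSV (gene_id <TAB> flag) into an AnnotationTable.

    A first line whose second field is not parseable as a boolean is taken as
    a header naming the category. Duplicate rows with consistent flags are
    deduplicated; conflicting duplicates are an error.
    """
    category = "flag"
    entries: dict[str, bool] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"line {lineno}: expected 2 tab-separated fields")
            gid, token = parts[0].strip(), parts[1]
            flag = _parse_flag(token)
            if flag is None:
                if lineno == 1:
                    category = token.strip()
                    continue
                raise FormatError(f"line {lineno}: cannot parse flag {token!r}")
            if gid in entries and entries[gid] != flag:
                raise ValidationError(
                    f"conflicting annotation for gene {gid!r}"
                )
            entries[gid] = flag
    return AnnotationTable(
        flags=pd.Series(entries, dtype=bool), category=category
    )
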