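"""Readers, writers and validated containers for the pipeline's artifacts.

All tabular artifacts are plain TSV; trees are Newick.  Feature tables are
stored features-as-rows (the common amplicon convention) but either
orientation can be read.  A BIOM-style TSV export header line
(``# Constructed from ...``) is tolerated and skipped.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import skbio
import yaml

logger = logging.getLogger("isobiome")

DEFAULT_SEED = 20210113

SEX_LABELS = ("female", "male", "unknown")
STAGE_LABELS = ("incubating", "chick-rearing")

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")

ISOTOPE_COLUMNS = ("d13c", "d15n", "d34s")

_FLOAT_FMT = "%.10g"


def setup_logging(level: str = "INFO") -> None:
    """Configure stderr logging for the ``isobiome`` logger."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(getattr(logging, level.upper()))


class FeatureTable:
    """Samples x ASVs matrix of non-negative integer read counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows are samples, columns are features (ASVs).  Cell values must be
        non-negative integers.  Identifiers must be unique on both axes.
    """

    def __init__(self, counts: pd.DataFrame):
        counts = counts.copy()
        dup_s = counts.index[counts.index.duplicated()].unique().tolist()
        if dup_s:
            raise ValueError(f"duplicate sample ids: {dup_s}")
        dup_f = counts.columns[counts.columns.duplicated()].unique().tolist()
        if dup_f:
            raise ValueError(f"duplicate feature ids: {dup_f}")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValueError("feature table contains non-numeric cells")
        if arr.size:
            if np.any(~np.isfinite(arr.astype(float))):
                raise ValueError("feature table contains non-finite cells")
            if np.any(arr.astype(float) % 1 != 0):
                bad = np.argwhere(arr.astype(float) % 1 != 0)[0]
                raise ValueError(
                    "non-integer count at sample "
                    f"{counts.index[bad[0]]!r}, feature {counts.columns[bad[1]]!r}"
                )
            if np.any(arr < 0):
                bad = np.argwhere(arr < 0)[0]
                raise ValueError(
                    "negative count at sample "
                    f"{counts.index[bad[0]]!r}, feature {counts.columns[bad[1]]!r}"
                )
        self.counts = counts.astype(np.int64)
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)
        self.counts.index.name = None
        self.counts.columns.name = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_depths(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalized proportions; every row sums to 1.

        Raises if any sample has zero total reads (run QC first).
        """
        depths = self.sample_depths()
        if (depths == 0).any():
            empty = depths.index[depths == 0].tolist()
            raise ValueError(f"samples with zero reads: {empty}")
        return self.counts.div(depths, axis=0)

    def without_samples(self, ids: Iterable[str]) -> "FeatureTable":
        ids = set(ids)
        return FeatureTable(self.counts.loc[[s for s in self.sample_ids if s not in ids]])

    def without_features(self, ids: Iterable[str]) -> "FeatureTable":
        ids = set(ids)
        return FeatureTable(self.counts[[f for f in self.feature_ids if f not in ids]])

    def __eq__(self, other) -> bool:  # pragma: no cover - trivial
        return isinstance(other, FeatureTable) and self.counts.equals(other.counts)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<FeatureTable {self.shape[0]} samples x {self.shape[1]} features>"


def read_feature_table(path, orientation: str = "features") -> FeatureTable:
    """Read a TSV feature table.

    ``orientation`` says what the *rows* of the file are: ``"features"``
    (default, QIIME/BIOM TSV convention) or ``"samples"``.
    """
    if orientation not in ("features", "samples"):
        raise ValueError("orientation must be 'features' or 'samples'")
    text = Path(path).read_text()
    lines = text.splitlines()
    # Tolerate BIOM-export comment lines; the real header may itself start
    # with '#OTU ID', so only lines before the last leading '#' line that
    # contain no tab, or explicit "# Constructed from" banners, are dropped.
    start = 0
    while start < len(lines) and lines[start].startswith("#") and (
        "\t" not in lines[start] or lines[start].lower().startswith("# constructed")
    ):
        start += 1
    body = "\n".join(lines[start:])
    if body and body.split("\n", 1)[0].startswith("#"):
        body = body[1:]  # strip leading '#' from a '#OTU ID' style header
    df = pd.read_csv(_io.StringIO(body), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if orientation == "features":
        df = df.T
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path, orientation: str = "features") -> None:
    df = table.counts.T if orientation == "features" else table.counts
    label = "feature_id" if orientation == "features" else "sample_id"
    df.to_csv(path, sep="\t", index_label=label)


# ---------------------------------------------------------------------------
# Phylogenetic tree


def read_tree(path) -> skbio.TreeNode:
    """Read a rooted Newick tree; leaf labels are feature ids.

    Missing branch lengths default to 0 with a warning.  A trifurcating
    (unrooted-style) root is resolved by midpoint rooting, with a warning.
    """
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises NewickFormatError subclasses
        raise ValueError(f"cannot parse Newick file {path}: {exc}") from exc
    missing = [n for n in tree.traverse(include_self=False) if n.length is None]
    if missing:
        logger.warning(
            "%d edges lack a branch length; defaulting to 0", len(missing)
        )
        for n in missing:
            n.length = 0.0
    if tree.length is None:
        tree.length = 0.0
    if len(tree.children) > 2:
        logger.warning(
            "root has %d children (unrooted-style tree); midpoint rooting",
            len(tree.children),
        )
        tree = tree.root_at_midpoint()
        for n in tree.traverse(include_self=True):
            if n.length is None:
                n.length = 0.0
    leaves = [t.name for t in tree.tips()]
    if len(set(leaves)) != len(leaves):
        raise ValueError("tree leaf labels are not unique")
    return tree


def write_tree(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Sample metadata


def _canon_label(value: str) -> str:
    return str(value).strip().lower().replace("_", "-").replace(" ", "-")


_TRUTHY = {"true", "1", "yes", "y", "t"}
_FALSY = {"false", "0", "no", "n", "f", "", "nan"}


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV into a DataFrame indexed by ``sample_id``.

    Required columns: sample_id, bird_id, sex, stage, sampling_point.
    Optional: is_negative_control (default False).  Categorical labels are
    normalized case-insensitively; unknown labels are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["sample_id", "bird_id", "sex", "stage", "sampling_point"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"metadata is missing required column(s): {missing}")
    if "is_negative_control" not in df.columns:
        df["is_negative_control"] = "false"

    def to_bool(v: str) -> bool:
        v = str(v).strip().lower()
        if v in _TRUTHY:
            return True
        if v in _FALSY:
            return False
        raise ValueError(f"unrecognized is_negative_control value {v!r}")

    df["is_negative_control"] = df["is_negative_control"].map(to_bool)

    out = df.set_index("sample_id")
    if out.index.duplicated().any():
        dups = out.index[out.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")

    for i, row in out.iterrows():
        ctrl = row["is_negative_control"]
        sex = _canon_label(row["sex"]) or ("unknown" if ctrl else "")
        if sex not in SEX_LABELS:
            raise ValueError(
                f"sample {i!r}: unknown sex {row['sex']!r}; accepted: {SEX_LABELS}"
            )
        out.at[i, "sex"] = sex
        stage = _canon_label(row["stage"])
        if stage == "chick-rearing" or stage == "chickrearing":
            stage = "chick-rearing"
        if not ctrl and stage not in STAGE_LABELS:
            raise ValueError(
                f"sample {i!r}: unknown stage {row['stage']!r}; accepted: {STAGE_LABELS}"
            )
        out.at[i, "stage"] = stage if stage in STAGE_LABELS else ""
        sp = str(row["sampling_point"]).strip()
        if not ctrl:
            if sp not in ("1", "2"):
                raise ValueError(
                    f"sample {i!r}: sampling_point must be 1 or 2, got {sp!r}"
                )
            if not str(row["bird_id"]).strip():
                raise ValueError(f"non-control sample {i!r} lacks bird_id")
        out.at[i, "sampling_point"] = int(sp) if sp in ("1", "2") else 0
    out["sampling_point"] = out["sampling_point"].astype(int)
    return out


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Isotope table


def read_isotopes(path) -> pd.DataFrame:
    """Read per-bird isotope TSV into a DataFrame indexed by ``bird_id``.

    Columns d13C (permil vs VPDB), d15N (vs AIR), d34S (vs VCDT); unicode
    delta spellings are accepted.
    """
    df = pd.read_csv(path, sep="\t")
    rename = {}
    for c in df.columns:
        key = (
            str(c).strip().lower().replace("δ", "d").replace("delta", "d").replace(" ", "")
        )
        rename[c] = key
    df = df.rename(columns=rename)
    missing = [c for c in ("bird_id",) + ISOTOPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"isotope table missing column(s): {missing}")
    df["bird_id"] = df["bird_id"].astype(str)
    out = df.set_index("bird_id")[list(ISOTOPE_COLUMNS)].astype(float)
    if out.index.duplicated().any():
        dups = out.index[out.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate bird ids in isotope table: {dups}")
    return out


def write_isotopes(iso: pd.DataFrame, path) -> None:
    iso.to_csv(path, sep="\t", index_label="bird_id", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Taxonomy


def read_taxonomy(path) -> pd.DataFrame:
    """Read a taxonomy TSV (feature_id, lineage[, confidence]).

    The lineage is a semicolon-separated string, domain first.  Missing ranks
    are explicit empty strings; rank prefixes like ``d__`` are stripped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    if "feature_id" not in df.columns or "lineage" not in df.columns:
        raise ValueError("taxonomy table requires columns: feature_id, lineage")
    rows = {}
    for _, row in df.iterrows():
        parts = [p.strip() for p in str(row["lineage"]).split(";")]
        parts = [p.split("__", 1)[1] if "__" in p[:4] else p for p in parts]
        parts += [""] * (len(TAXONOMY_RANKS) - len(parts))
        rec = dict(zip(TAXONOMY_RANKS, parts[: len(TAXONOMY_RANKS)]))
        rec["confidence"] = float(row["confidence"]) if str(row.get("confidence", "")).strip() else np.nan
        rows[str(row["feature_id"])] = rec
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "feature_id"
    return out


def write_taxonomy(tax: pd.DataFrame, path) -> None:
    lineage = tax[list(TAXONOMY_RANKS)].agg(";".join, axis=1)
    out = pd.DataFrame({"feature_id": tax.index, "lineage": lineage.values})
    if "confidence" in tax.columns:
        out["confidence"] = tax["confidence"].values
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def lineage_contains(tax: pd.DataFrame, feature_id: str, name: str) -> bool:
    """Case-insensitive membership of ``name`` at any rank of a lineage."""
    if feature_id not in tax.index:
        return False
    row = tax.loc[feature_id, list(TAXONOMY_RANKS)]
    return any(str(v).strip().lower() == name.lower() for v in row)


# ---------------------------------------------------------------------------
# Distance matrices & config


def read_distance_matrix(path) -> skbio.DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return skbio.DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])


def write_distance_matrix(dm: skbio.DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="sample_id", float_format=_FLOAT_FMT
    )


def load_config(path) -> dict:
    """Load a YAML config; guarantees a ``seed`` key (default 20210113)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    cfg.setdefault("seed", DEFAULT_SEED)
    return cfg
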