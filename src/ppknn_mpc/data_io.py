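"""Multi-owner input sharing, file formats, and synthetic medical records.

Datasets are plain CSV: integer feature columns ``f1..fm`` and a 1-based
``label`` column in {1..v}; record ids are 0-based row positions.  Owners
hold either horizontal partitions (disjoint record blocks with the full
schema) or vertical partitions (disjoint attribute sets over identical
record ids).  The input sharing phase turns owner plaintext into one
shared global dataset held by the simulated servers; owners never see each
other's plaintext — each owner's rows/columns pass through their own
sharing call, and only shares reach the engine's dataset.

Share files (one CSV per server) carry columns
``record_id, slot_name, share_value`` where slots are ``f1..fm`` for
features and ``class1..classv`` for one-hot class bits.

The synthetic generator stands in for hospitals' case libraries: per-class
cluster centers in feature space, integer features drawn around the
owning class's center with a configurable spread, clipped to [0, 2^b).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import MPCEngine
from .errors import FormatError, ParameterError, PartitionError, RangeError
from .field import DEFAULT_KAPPA, DEFAULT_PRIME
from .knn import SharedQuery, SharedRecord
from .sharing import ShareVector, reconstruct

HORIZONTAL = "horizontal"
VERTICAL = "vertical"


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------
@dataclass
class RunConfig:
    """JSON-serializable protocol run configuration."""

    n_servers: int = 5
    threshold: int = 2
    prime: int = DEFAULT_PRIME
    kappa: int = DEFAULT_KAPPA
    bits: int = 33
    k: int = 100
    seed: int = 0
    mode: str = "public_cnt"
    tie_mode: str = "index_augment"

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        return cls(**{k: d[k] for k in cls().__dict__ if k in d})

    def make_engine(self) -> MPCEngine:
        from .field import FieldConfig

        fc = FieldConfig(p=self.prime,
                         eval_points=tuple(range(1, self.n_servers + 1)),
                         kappa=self.kappa)
        return MPCEngine(n_parties=self.n_servers, threshold=self.threshold,
                         field=fc, seed=self.seed)


# ---------------------------------------------------------------------------
# dataset / query CSV
# ---------------------------------------------------------------------------
def feature_columns(m: int) -> list[str]:
    return [f"f{j}" for j in range(1, m + 1)]


def _validate_int_cell(value, row: int, col: str) -> int:
    try:
        f = float(value)
        i = int(f)
        if f != i:
            raise ValueError
    except (TypeError, ValueError):
        raise FormatError(f"non-integer value {value!r} in column {col}",
                          row=row) from None
    return i


def validate_dataset(df: pd.DataFrame, v: int | None = None) -> pd.DataFrame:
    cols = [c for c in df.columns if c.startswith("f")]
    if not cols or "label" not in df.columns:
        raise FormatError(
            "dataset needs feature columns f1..fm and a label column"
        )
    out = pd.DataFrame(index=df.index)
    for col in cols + ["label"]:
        out[col] = [
            _validate_int_cell(x, row, col)
            for row, x in enumerate(df[col].tolist())
        ]
    for row, lab in enumerate(out["label"].tolist()):
        if lab < 1 or (v is not None and lab > v):
            raise FormatError(
                f"label {lab} outside {{1..{v if v else '...'}}} "
                "(labels are 1-based)", row=row)
    neg = out[cols].lt(0).any(axis=1)
    if neg.any():
        raise FormatError("negative feature value",
                          row=int(neg[neg].index[0]))
    return out


def read_dataset(path: str | Path, v: int | None = None) -> pd.DataFrame:
    return validate_dataset(pd.read_csv(path), v=v)


def write_dataset(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_query(path: str | Path) -> list[int]:
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("f")]
    if not cols or len(df) != 1:
        raise FormatError("query CSV needs one row of feature columns f1..fm")
    return [_validate_int_cell(df.iloc[0][c], 0, c) for c in cols]


def write_query(features: list[int], path: str | Path) -> None:
    pd.DataFrame([features], columns=feature_columns(len(features))).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# owners and the input sharing phase
# ---------------------------------------------------------------------------
@dataclass
class OwnerDataset:
    """One data owner's plaintext slice of the global dataset.

    Horizontal: ``table`` holds full-schema rows (f1..fm + label) and
    ``record_ids`` the global 0-based ids of those rows.
    Vertical: ``table`` holds a subset of columns (some features and/or the
    label) for every record id.
    """

    owner_id: str
    partition: str  # HORIZONTAL | VERTICAL
    table: pd.DataFrame
    record_ids: list[int] = dc_field(default_factory=list)

    def __post_init__(self):
        if self.partition not in (HORIZONTAL, VERTICAL):
            raise PartitionError(f"unknown partition {self.partition!r}")
        if not self.record_ids:
            self.record_ids = list(range(len(self.table)))


def split_horizontal(df: pd.DataFrame, sizes: list[int]) -> list[OwnerDataset]:
    """Cut a global dataset into consecutive owner blocks."""
    if sum(sizes) != len(df):
        raise PartitionError("block sizes must sum to the dataset size")
    owners, start = [], 0
    for i, sz in enumerate(sizes):
        owners.append(OwnerDataset(
            owner_id=f"owner{i}", partition=HORIZONTAL,
            table=df.iloc[start:start + sz].reset_index(drop=True),
            record_ids=list(range(start, start + sz)),
        ))
        start += sz
    return owners


def split_vertical(df: pd.DataFrame, column_groups: list[list[str]]
                   ) -> list[OwnerDataset]:
    """Assign disjoint column sets (features and/or label) to owners."""
    seen: set[str] = set()
    for grp in column_groups:
        if seen & set(grp):
            raise PartitionError("overlapping vertical column groups")
        seen |= set(grp)
    if seen != set(df.columns):
        raise PartitionError("vertical groups must cover every column")
    return [
        OwnerDataset(owner_id=f"owner{i}", partition=VERTICAL,
                     table=df[grp].copy(),
                     record_ids=list(range(len(df))))
        for i, grp in enumerate(column_groups)
    ]


def _assemble_global(owners: list[OwnerDataset]) -> pd.DataFrame:
    kinds = {o.partition for o in owners}
    if len(kinds) != 1:
        raise PartitionError("owners mix horizontal and vertical partitions")
    if kinds == {HORIZONTAL}:
        schema = None
        rows: dict[int, pd.Series] = {}
        for o in owners:
            cols = tuple(o.table.columns)
            if schema is None:
                schema = cols
            elif cols != schema:
                raise PartitionError(
                    f"owner {o.owner_id} has a different schema"
                )
            if len(o.record_ids) != len(o.table):
                raise PartitionError("record_ids/table length mismatch")
            for rid, (_, row) in zip(o.record_ids, o.table.iterrows()):
                if rid in rows:
                    raise PartitionError(f"record id {rid} owned twice")
                rows[rid] = row
        n = len(rows)
        if sorted(rows) != list(range(n)):
            raise PartitionError("record ids are not contiguous from 0")
        return pd.DataFrame([rows[i] for i in range(n)]).reset_index(drop=True)
    # vertical
    ids = None
    pieces = []
    seen_cols: set[str] = set()
    for o in owners:
        if ids is None:
            ids = list(o.record_ids)
        elif list(o.record_ids) != ids:
            raise PartitionError("vertical owners disagree on record ids")
        overlap = seen_cols & set(o.table.columns)
        if overlap:
            raise PartitionError(f"columns owned twice: {sorted(overlap)}")
        seen_cols |= set(o.table.columns)
        pieces.append(o.table.reset_index(drop=True))
    glob = pd.concat(pieces, axis=1)
    if "label" not in glob.columns:
        raise PartitionError("no owner holds the label column")
    m = sum(1 for c in glob.columns if c.startswith("f"))
    return glob[feature_columns(m) + ["label"]]


def share_owner_datasets(
    owners: list[OwnerDataset], engine: MPCEngine, v: int
) -> list[SharedRecord]:
    """Input sharing phase: owner plaintext -> one shared global dataset.

    Each owner shares its own cells; the servers end up holding exactly one
    SharedRecord per global record id, features plus one-hot class bits.
    """
    glob = _assemble_global(owners)
    glob = validate_dataset(glob, v=v)
    return share_plaintext_dataset(glob, engine, v)


def share_plaintext_dataset(
    df: pd.DataFrame, engine: MPCEngine, v: int
) -> list[SharedRecord]:
    cols = [c for c in df.columns if c.startswith("f")]
    records = []
    for _, row in df.iterrows():
        feats = [engine.share_secret(int(row[c])) for c in cols]
        label = int(row["label"])
        if not 1 <= label <= v:
            raise RangeError(f"label {label} outside {{1..{v}}}")
        onehot = [engine.share_secret(1 if j == label else 0)
                  for j in range(1, v + 1)]
        records.append(SharedRecord(features=feats, class_onehot=onehot))
    return records


def share_query(features: list[int], engine: MPCEngine) -> SharedQuery:
    return SharedQuery(
        features=[engine.share_secret(int(q)) for q in features]
    )


# ---------------------------------------------------------------------------
# share files (one CSV per simulated server)
# ---------------------------------------------------------------------------
def write_share_files(
    records: list[SharedRecord], outdir: str | Path, n_servers: int
) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in range(n_servers):
        rows = []
        for rid, rec in enumerate(records):
            for j, sv in enumerate(rec.features, start=1):
                rows.append((rid, f"f{j}", sv.shares[s]))
            for j, sv in enumerate(rec.class_onehot, start=1):
                rows.append((rid, f"class{j}", sv.shares[s]))
        path = outdir / f"server{s}.csv"
        pd.DataFrame(rows, columns=["record_id", "slot_name", "share_value"]
                     ).to_csv(path, index=False)
        paths.append(path)
    return paths


def read_share_files(
    indir: str | Path, n_servers: int, degree_bound: int
) -> list[SharedRecord]:
    frames = [
        pd.read_csv(Path(indir) / f"server{s}.csv") for s in range(n_servers)
    ]
    base = frames[0]
    records = []
    for rid in sorted(base["record_id"].unique()):
        feats, onehot = {}, {}
        sel = base[base["record_id"] == rid]
        for slot in sel["slot_name"]:
            shares = tuple(
                int(f.loc[(f["record_id"] == rid) & (f["slot_name"] == slot),
                          "share_value"].iloc[0])
                for f in frames
            )
            sv = ShareVector(shares=shares, degree_bound=degree_bound)
            if slot.startswith("f"):
                feats[int(slot[1:])] = sv
            elif slot.startswith("class"):
                onehot[int(slot[5:])] = sv
            else:
                raise FormatError(f"unknown slot {slot!r}")
        records.append(SharedRecord(
            features=[feats[j] for j in sorted(feats)],
            class_onehot=[onehot[j] for j in sorted(onehot)],
        ))
    return records


def reconstruct_dataset(
    records: list[SharedRecord], engine: MPCEngine
) -> pd.DataFrame:
    """Audit aid: recombine a shared dataset back to plaintext."""
    rows = []
    for rec in records:
        feats = [reconstruct(sv, engine.field) for sv in rec.features]
        bits = [reconstruct(sv, engine.field) for sv in rec.class_onehot]
        if sum(bits) != 1:
            raise RangeError("class vector is not one-hot")
        rows.append(feats + [bits.index(1) + 1])
    m = len(records[0].features)
    return pd.DataFrame(rows, columns=feature_columns(m) + ["label"])


# ---------------------------------------------------------------------------
# synthetic medical records
# ---------------------------------------------------------------------------
@dataclass
class SynthConfig:
    """Clustered integer symptom records, one cluster per diagnosis class.

    Defaults model a small case library: 30 records, 4 quantized symptom
    features of 4 bits each, 3 diagnosis classes whose centers sit evenly
    spaced along the feature range, and an integer-rounded Gaussian spread
    of 1 quantization step around the owning class's center.
    """

    n_data: int = 30
    m: int = 4
    v: int = 3
    feature_bits: int = 4
    cluster_centers: list[list[int]] | None = None
    spread: float = 1.0
    seed: int = 0

    def centers(self) -> np.ndarray:
        if self.cluster_centers is not None:
            c = np.asarray(self.cluster_centers, dtype=np.int64)
            if c.shape != (self.v, self.m):
                raise ParameterError(
                    f"cluster_centers must be shape ({self.v}, {self.m})"
                )
            return c
        top = (1 << self.feature_bits) - 1
        vals = [int(np.floor((2 * j + 1) * top / (2 * self.v) + 0.5))
                for j in range(self.v)]
        return np.asarray([[val] * self.m for val in vals], dtype=np.int64)


def generate_synthetic(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a plaintext dataset plus one held-out query per class.

    Class labels are assigned round-robin then shuffled, so every class has
    at least one record whenever n_data >= v.  The held-out queries are the
    class centers themselves.
    """
    if cfg.n_data < 1 or cfg.m < 1 or cfg.v < 1:
        raise ParameterError("n_data, m, v must be positive")
    rng = np.random.default_rng(cfg.seed)
    centers = cfg.centers()
    hi = (1 << cfg.feature_bits) - 1
    if centers.min() < 0 or centers.max() > hi:
        raise ParameterError("cluster centers outside [0, 2^b)")

    labels = np.array([(i % cfg.v) + 1 for i in range(cfg.n_data)])
    rng.shuffle(labels)
    noise = rng.normal(0.0, cfg.spread, size=(cfg.n_data, cfg.m))
    feats = np.clip(np.rint(centers[labels - 1] + noise), 0, hi).astype(int)

    df = pd.DataFrame(feats, columns=feature_columns(cfg.m))
    df["label"] = labels
    queries = pd.DataFrame(centers, columns=feature_columns(cfg.m))
    queries["label"] = np.arange(1, cfg.v + 1)
    return df, queries
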