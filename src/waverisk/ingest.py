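"""Reading expression/clinical tables, endpoint labelling, gene filtering and split plans.

Expression matrices are carried as pandas DataFrames oriented genes x samples
(gene identifiers in the index, sample identifiers in the columns). Clinical
tables are DataFrames with one row per sample and the columns
``sample_id``, ``os_days``, ``vital_status`` and ``tumor_stage``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

THREE_YEARS_DAYS = 1095.0

_STAGE_RE = re.compile(r"^(?:stage\s*)?(iv|iii|ii|i|[1-4])\s*[a-c]?[0-9]?$", re.IGNORECASE)
_ROMAN = {"i": "I", "ii": "II", "iii": "III", "iv": "IV", "1": "I", "2": "II", "3": "III", "4": "IV"}

CLINICAL_COLUMNS = ("sample_id", "os_days", "vital_status", "tumor_stage")


@dataclass
class LabeledCohort:
    """Samples with a binary risk label for one endpoint plus survival follow-up.

    ``labels`` uses 1 for the high-risk (positive) class. ``endpoint`` is
    either ``"stage"`` (tumor stage III/IV vs I/II) or ``"survival3y"``
    (death before the horizon vs survival beyond it).
    """

    sample_ids: np.ndarray
    labels: np.ndarray
    endpoint: str
    os_days: np.ndarray
    event: np.ndarray
    removed_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=int)
        self.os_days = np.asarray(self.os_days, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not (len(self.sample_ids) == len(self.labels) == len(self.os_days) == len(self.event)):
            raise ValueError("cohort fields must have equal length")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "label": self.labels,
                "os_days": self.os_days,
                "event": self.event,
            }
        )


@dataclass
class SplitPlan:
    """Repeated random 70/30-style splits, reproducible from a seed."""

    repeats: int
    train_fraction: float
    seed: int
    splits: list  # list of (train_ids, validation_ids) ndarray pairs

    def __iter__(self):
        return iter(self.splits)

    def __len__(self):
        return len(self.splits)


def _read_table(path, sep=None) -> pd.DataFrame:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def read_expression(path, dialect: str = "genes-in-rows", sep=None) -> pd.DataFrame:
    """Read a delimited expression table and orient it genes x samples.

    Parameters
    ----------
    path : str or file-like
        Delimited text with one header row and identifier first column.
    dialect : {"genes-in-rows", "genes-in-columns"}
        Orientation of the stored table; the returned frame always has
        genes in the index.
    """
    if dialect not in ("genes-in-rows", "genes-in-columns"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_table(path, sep=sep)
    if dialect == "genes-in-columns":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None

    for axis, name in ((df.index, "gene"), (df.columns, "sample")):
        dup = axis[axis.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate {name} identifiers: {dup}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric expression value {df.iat[r, c]!r} at gene "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    neg = numeric.to_numpy() < 0
    if neg.any():
        r, c = np.argwhere(neg)[0]
        raise ValueError(
            f"negative expression value {numeric.iat[r, c]} at gene "
            f"{numeric.index[r]!r}, sample {numeric.columns[c]!r}"
        )
    return numeric.astype(float)


def read_clinical(path, sep=None) -> pd.DataFrame:
    """Read a clinical table with sample_id, os_days, vital_status, tumor_stage."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns and c != "tumor_stage"]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    if "tumor_stage" not in df.columns:
        df["tumor_stage"] = np.nan
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id in clinical table: {dup}")
    return df


def filter_low_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Drop genes whose expression is zero in over half of the samples.

    The rule is strict: a gene that is zero in exactly half of the samples
    is kept. Gene order is preserved.
    """
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise ValueError("empty expression matrix")
    n = expr.shape[1]
    zero_counts = (expr.to_numpy() == 0).sum(axis=1)
    # strict "over half": remove when zero_count > n/2, keep the n/2 boundary
    keep = zero_counts <= n / 2
    out = expr.loc[keep]
    if out.shape[0] == 0:
        raise ValueError(
            "all genes were zero in over half of the samples; check the input matrix"
        )
    return out


def normalize_stage(stage) -> str | None:
    """Map a free-form stage string ('Stage IIIA', 'iv', '2') to I/II/III/IV."""
    if stage is None or (isinstance(stage, float) and np.isnan(stage)):
        return None
    m = _STAGE_RE.match(str(stage).strip())
    if not m:
        return None
    return _ROMAN[m.group(1).lower()]


def derive_stage_labels(clinical: pd.DataFrame) -> LabeledCohort:
    """Label samples by tumor stage: III/IV high-risk (1), I/II low-risk (0).

    Samples with missing or unparseable stage are excluded (and logged).
    """
    ids, labels, os_days, event, removed = [], [], [], [], []
    for row in clinical.itertuples(index=False):
        stage = normalize_stage(row.tumor_stage)
        if stage is None:
            removed.append(row.sample_id)
            continue
        ids.append(row.sample_id)
        labels.append(1 if stage in ("III", "IV") else 0)
        os_days.append(float(row.os_days))
        event.append(1 if str(row.vital_status).lower() == "dead" else 0)
    if removed:
        logger.info("derive_stage_labels: excluded %d samples with missing/unparseable stage", len(removed))
    return LabeledCohort(ids, labels, "stage", os_days, event, removed_ids=removed)


def derive_survival_labels(clinical: pd.DataFrame, horizon_days: float = THREE_YEARS_DAYS) -> LabeledCohort:
    """Label samples by survival at a horizon (default 3 years = 1095 days).

    Death before the horizon -> high risk (1); follow-up reaching the horizon
    -> low risk (0) regardless of vital status; alive with follow-up shorter
    than the horizon -> removed (their 3-year status is unknown).
    """
    ids, labels, os_days, event, removed = [], [], [], [], []
    for row in clinical.itertuples(index=False):
        t = float(row.os_days)
        dead = str(row.vital_status).lower() == "dead"
        if t < horizon_days and not dead:
            removed.append(row.sample_id)
            continue
        ids.append(row.sample_id)
        labels.append(1 if (t < horizon_days and dead) else 0)
        os_days.append(t)
        event.append(1 if dead else 0)
    if removed:
        logger.info("derive_survival_labels: removed %d alive samples censored before the horizon", len(removed))
    cohort = LabeledCohort(ids, labels, "survival3y", os_days, event, removed_ids=removed)
    counts = np.bincount(cohort.labels, minlength=2)
    if counts.min() < 2:
        raise ValueError(
            f"fewer than 2 samples in a class after horizon filtering (counts {counts.tolist()})"
        )
    return cohort


def make_splits(
    cohort: LabeledCohort,
    train_fraction: float = 0.7,
    repeats: int = 100,
    seed: int = 0,
    max_redraws: int = 100,
) -> SplitPlan:
    """Repeated random train/validation splits by uniform sampling without replacement.

    Train size is floor(train_fraction * n). Splits leaving a class empty in
    either part are redrawn (bounded); the plan is reproducible from the seed.
    """
    n = len(cohort)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    counts = np.bincount(cohort.labels, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class to split")
    n_train = int(np.floor(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError("train_fraction leaves an empty train or validation set")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(repeats):
        for _attempt in range(max_redraws):
            perm = rng.permutation(n)
            tr, va = perm[:n_train], perm[n_train:]
            if len(set(cohort.labels[tr])) == 2 and len(set(cohort.labels[va])) == 2:
                break
        else:
            raise RuntimeError("could not draw a split with both classes in each part")
        splits.append((cohort.sample_ids[np.sort(tr)], cohort.sample_ids[np.sort(va)]))
    return SplitPlan(repeats=repeats, train_fraction=train_fraction, seed=seed, splits=splits)
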