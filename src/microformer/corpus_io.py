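"""Abundance-table input/output, corpus filtering, and vocabulary construction.

The universal input is a genus-level relative-abundance table: rows are
samples, columns are genera, cells are fractions in [0, 1]. Tables travel as
plain TSV (header ``sample_id<TAB>genus...``), metadata as a two-column TSV
mapping sample id to a group label.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "Vocabulary",
    "read_abundance_tsv",
    "write_abundance_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "filter_corpus",
    "build_vocab",
]

#: default per-sample abundance floor: 0.01% relative abundance
MIN_REL_ABUND = 1e-4
#: default minimum count of non-negligible genera a sample must retain
MIN_GENERA = 10

SPECIAL_TOKENS = ("pad", "bos", "eos", "unk")


class TableValidationError(ValueError):
    """Raised when an abundance table violates its invariants."""


class TableParseError(ValueError):
    """Raised when a TSV cell cannot be interpreted as a number."""


@dataclass
class AbundanceTable:
    """Samples x genera relative abundances with optional per-sample labels.

    ``values[i, j]`` is the relative abundance of ``genus_names[j]`` in
    ``sample_ids[i]``. Rows need not sum to one unless renormalized.
    """

    sample_ids: list[str]
    genus_names: list[str]
    values: np.ndarray
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise TableValidationError("values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.genus_names)):
            raise TableValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.genus_names)} genera"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise TableValidationError(f"duplicate sample ids: {dupes[:5]}")
        if len(set(self.genus_names)) != len(self.genus_names):
            raise TableValidationError("duplicate genus names")
        if self.values.size and self.values.min() < 0:
            raise TableValidationError("negative abundance values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genera(self) -> int:
        return len(self.genus_names)

    def renormalized(self) -> "AbundanceTable":
        """Return a copy whose rows each sum to one (zero rows left as is)."""
        sums = self.values.sum(axis=1, keepdims=True)
        safe = np.where(sums > 0, sums, 1.0)
        return AbundanceTable(
            list(self.sample_ids), list(self.genus_names), self.values / safe,
            dict(self.labels) if self.labels else None,
        )

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.genus_names)

    def label_list(self) -> list[str]:
        if self.labels is None:
            raise TableValidationError("table has no labels")
        missing = [s for s in self.sample_ids if s not in self.labels]
        if missing:
            raise TableValidationError(f"samples without label: {missing[:5]}")
        return [self.labels[s] for s in self.sample_ids]


def read_abundance_tsv(path: str | Path, renormalize: bool = False,
                       labels_path: str | Path | None = None) -> AbundanceTable:
    """Read an abundance TSV (header of genus names, first column sample id).

    Any cell that does not parse as a number raises :class:`TableParseError`
    naming the offending sample and genus. With ``renormalize`` each row is
    divided by its sum.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().values)
    if bad.size:
        i, j = bad[0]
        raise TableParseError(
            f"non-numeric cell {df.iloc[i, j]!r} at sample {df.index[i]!r}, "
            f"genus {df.columns[j]!r} in {path}"
        )
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise TableValidationError(f"duplicate sample ids in {path}: {dupes[:5]}")
    labels = read_metadata_tsv(labels_path) if labels_path else None
    table = AbundanceTable(
        [str(s) for s in df.index], [str(g) for g in df.columns],
        numeric.values.astype(float), labels,
    )
    return table.renormalized() if renormalize else table


def write_abundance_tsv(table: AbundanceTable, path: str | Path) -> None:
    df = table.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_metadata_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>label`` metadata file."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise TableParseError(f"metadata {path} needs two columns (sample_id, label)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_metadata_tsv(labels: dict[str, str], path: str | Path) -> None:
    pd.DataFrame({"sample_id": list(labels), "label": list(labels.values())}).to_csv(
        path, sep="\t", index=False
    )


def filter_corpus(table: AbundanceTable, min_rel_abund: float = MIN_REL_ABUND,
                  min_genera: int = MIN_GENERA, renormalize: bool = True) -> AbundanceTable:
    """Apply the corpus filters: zero negligible abundances, drop thin samples.

    Per sample, genera below ``min_rel_abund`` are zeroed; samples left with
    fewer than ``min_genera`` nonzero genera are dropped; surviving rows are
    renormalized over the retained genera (disable with ``renormalize=False``).
    Idempotent: renormalization can only increase retained abundances, so a
    second pass zeroes nothing new.
    """
    vals = table.values.copy()
    vals[vals < min_rel_abund] = 0.0
    keep = (vals > 0).sum(axis=1) >= min_genera
    if not keep.any():
        warnings.warn("all samples dropped by corpus filter", stacklevel=2)
    sample_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    vals = vals[keep]
    labels = None
    if table.labels is not None:
        labels = {s: table.labels[s] for s in sample_ids if s in table.labels}
    out = AbundanceTable(sample_ids, list(table.genus_names), vals, labels)
    return out.renormalized() if renormalize else out


@dataclass
class Vocabulary:
    """Genus <-> token-id map with special tokens and optional label tokens.

    Ids are contiguous: specials first (pad=0, bos=1, eos=2, unk=3), then
    genera, then any label tokens appended at the end. Extending the
    vocabulary never reindexes existing tokens.
    """

    genus_to_id: dict[str, int]
    special: dict[str, int] = field(
        default_factory=lambda: {name: i for i, name in enumerate(SPECIAL_TOKENS)}
    )
    label_tokens: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = (list(self.special.values()) + list(self.genus_to_id.values())
               + list(self.label_tokens.values()))
        if len(set(ids)) != len(ids):
            raise TableValidationError("overlapping token ids in vocabulary")
        if sorted(ids) != list(range(len(ids))):
            raise TableValidationError("token ids must be contiguous from 0")
        self._id_to_genus = {i: g for g, i in self.genus_to_id.items()}
        self._id_to_label = {i: l for l, i in self.label_tokens.items()}

    @property
    def size(self) -> int:
        return len(self.special) + len(self.genus_to_id) + len(self.label_tokens)

    @property
    def pad_id(self) -> int:
        return self.special["pad"]

    @property
    def bos_id(self) -> int:
        return self.special["bos"]

    @property
    def eos_id(self) -> int:
        return self.special["eos"]

    @property
    def unk_id(self) -> int:
        return self.special["unk"]

    def id_for(self, genus: str) -> int:
        return self.genus_to_id.get(genus, self.unk_id)

    def genus_for(self, token_id: int) -> str | None:
        """Genus name for an id, or None for special/label tokens."""
        return self._id_to_genus.get(token_id)

    def label_for(self, token_id: int) -> str | None:
        return self._id_to_label.get(token_id)

    def is_special(self, token_id: int) -> bool:
        return token_id in set(self.special.values())

    def genus_ids(self) -> np.ndarray:
        return np.array(sorted(self.genus_to_id.values()), dtype=int)

    def to_json(self) -> str:
        return json.dumps(
            {"genera": self.genus_to_id, "special": self.special,
             "labels": self.label_tokens},
            indent=1, sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        obj = json.loads(text)
        return cls(dict(obj["genera"]), dict(obj["special"]), dict(obj.get("labels", {})))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        return cls.from_json(Path(path).read_text())


def build_vocab(table: AbundanceTable) -> Vocabulary:
    """One token per genus observed (nonzero) in at least one sample.

    Genera are assigned ids in order of descending prevalence (number of
    samples with nonzero abundance), ties broken lexicographically, so the
    mapping is deterministic and frequent genera get small ids.
    """
    prevalence = (table.values > 0).sum(axis=0)
    observed = [(int(-prevalence[j]), g) for j, g in enumerate(table.genus_names)
                if prevalence[j] > 0]
    observed.sort()
    offset = len(SPECIAL_TOKENS)
    genus_to_id = {g: offset + rank for rank, (_, g) in enumerate(observed)}
    return Vocabulary(genus_to_id)
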