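"""Core domain types and file I/O.

Holds the drug universe, set-valued feature profiles, per-channel similarity
matrices, the known-combination network, labeled pair datasets and the run
configuration, plus readers/writers for the plain-text exchange formats
(square similarity TSV/CSV, two-column pair lists, GMT-like or long-format
profiles, and the evaluation report table).

Pairs are always stored canonically (lexicographically smaller id first) and
all pair keys are unordered.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger("drugcombo")

#: tolerance for accepting a slightly asymmetric similarity matrix on read
ASYMMETRY_TOL = 1e-6

MISSING_POLICIES = ("zero", "drop", "error")


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair ``{a, b}`` with the smaller id first."""
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class DrugSet:
    """Ordered universe of drug identifiers; order fixes matrix row order."""

    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) < 2:
            raise ValueError("a DrugSet needs at least 2 drugs")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({d for d in self.ids if self.ids.count(d) > 1})
            raise ValueError(f"duplicate drug ids: {dupes}")
        object.__setattr__(self, "ids", tuple(str(d) for d in self.ids))

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, drug: object) -> bool:
        return drug in self._index

    def __iter__(self):
        return iter(self.ids)

    @property
    def _index(self) -> dict[str, int]:
        # cached lazily on the instance; frozen dataclass so stash via __dict__
        idx = self.__dict__.get("_index_cache")
        if idx is None:
            idx = {d: i for i, d in enumerate(self.ids)}
            self.__dict__["_index_cache"] = idx
        return idx

    def index(self, drug: str) -> int:
        try:
            return self._index[drug]
        except KeyError:
            raise KeyError(f"unknown drug id: {drug!r}") from None


@dataclass(frozen=True)
class FeatureProfile:
    """Per-channel set-valued annotations: drug id -> finite token set.

    Empty token sets are kept explicitly; an annotation-free drug is recorded,
    not dropped.
    """

    channel: str
    members: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean = {str(d): frozenset(str(t).strip() for t in toks)
                 for d, toks in self.members.items()}
        object.__setattr__(self, "members", clean)

    def tokens(self, drug: str) -> frozenset[str]:
        return self.members.get(drug, frozenset())

    def drugs(self) -> tuple[str, ...]:
        return tuple(self.members)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric drug-by-drug similarity in [0, 1] with unit diagonal."""

    channel: str
    drugs: DrugSet
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.drugs)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} drugs")
        if not np.allclose(v, v.T, atol=ASYMMETRY_TOL, rtol=0):
            raise ValueError("similarity matrix is not symmetric")
        v = (v + v.T) / 2.0
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            i, j = np.unravel_index(np.argmax(np.abs(v - 0.5)), v.shape)
            raise ValueError(
                f"similarity out of [0,1] at ({self.drugs.ids[i]}, {self.drugs.ids[j]}): {v[i, j]}"
            )
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity diagonal must be exactly 1")
        np.fill_diagonal(v, 1.0)
        v = np.clip(v, 0.0, 1.0)
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.drugs.index(a), self.drugs.index(b)])


@dataclass(frozen=True)
class CombinationNetwork:
    """Known drug combinations as a symmetric binary adjacency."""

    drugs: DrugSet
    positive_pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], None] = {}
        for a, b in self.positive_pairs:
            p = canonical_pair(a, b)
            for d in p:
                if d not in self.drugs:
                    raise KeyError(f"pair drug {d!r} not in DrugSet")
            seen.setdefault(p, None)
        object.__setattr__(self, "positive_pairs", tuple(seen))

    @property
    def adjacency(self) -> np.ndarray:
        adj = self.__dict__.get("_adj_cache")
        if adj is None:
            n = len(self.drugs)
            adj = np.zeros((n, n), dtype=np.int8)
            for a, b in self.positive_pairs:
                i, j = self.drugs.index(a), self.drugs.index(b)
                adj[i, j] = adj[j, i] = 1
            adj.flags.writeable = False
            self.__dict__["_adj_cache"] = adj
        return adj

    @property
    def pair_set(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.positive_pairs)

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_pair(a, b) in self.pair_set

    def without_pairs(self, pairs: Iterable[tuple[str, str]]) -> "CombinationNetwork":
        """Copy of the network with the given unordered pairs removed."""
        drop = {canonical_pair(a, b) for a, b in pairs}
        kept = tuple(p for p in self.positive_pairs if p not in drop)
        return CombinationNetwork(self.drugs, kept)

    def without_drug(self, drug: str) -> "CombinationNetwork":
        """Copy with every edge touching ``drug`` removed (the drug stays)."""
        self.drugs.index(drug)
        kept = tuple(p for p in self.positive_pairs if drug not in p)
        return CombinationNetwork(self.drugs, kept)

    def non_edge_pairs(self) -> list[tuple[str, str]]:
        """All unordered non-self pairs without an edge, in row-major order."""
        ids = self.drugs.ids
        adj = self.adjacency
        iu, ju = np.triu_indices(len(ids), k=1)
        return [(ids[i], ids[j]) for i, j in zip(iu, ju) if not adj[i, j]]

    def n_non_edges(self) -> int:
        n = len(self.drugs)
        return n * (n - 1) // 2 - len(self.positive_pairs)


@dataclass(frozen=True)
class PairDataset:
    """Labeled drug pairs with one similarity value per declared channel."""

    pairs: tuple[tuple[str, str, int], ...]
    channels: tuple[str, ...]
    features: np.ndarray          # (n_pairs, n_channels) in [0, 1]
    missing: np.ndarray | None = None  # bool mask, same shape, True = imputed

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        pairs = []
        seen = set()
        for a, b, y in self.pairs:
            p = canonical_pair(a, b)
            if p in seen:
                raise ValueError(f"duplicate pair {p}")
            seen.add(p)
            if y not in (0, 1):
                raise ValueError(f"label must be 0/1, got {y!r} for {p}")
            pairs.append((p[0], p[1], int(y)))
        if feats.shape != (len(pairs), len(self.channels)):
            raise ValueError(
                f"feature shape {feats.shape} does not match "
                f"{len(pairs)} pairs x {len(self.channels)} channels"
            )
        if feats.size and (np.nanmin(feats) < -1e-12 or np.nanmax(feats) > 1 + 1e-12):
            raise ValueError("features must lie in [0, 1]")
        miss = self.missing
        if miss is None:
            miss = np.zeros(feats.shape, dtype=bool)
        else:
            miss = np.asarray(miss, dtype=bool)
            if miss.shape != feats.shape:
                raise ValueError("missing mask shape mismatch")
        feats.flags.writeable = False
        miss.flags.writeable = False
        object.__setattr__(self, "pairs", tuple(pairs))
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "missing", miss)

    @property
    def labels(self) -> np.ndarray:
        return np.array([y for _, _, y in self.pairs], dtype=int)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class RunConfig:
    """Settings of one evaluation run; the seed is recorded in every output."""

    channels: tuple[str, ...] = ()
    k: int = 5
    ratio: int = 1
    repeats: int = 20
    threshold: float = 0.5
    seed: int = 0
    missing_policy: str = "zero"

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.ratio < 1:
            raise ValueError("negative:positive ratio must be >= 1")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.missing_policy not in MISSING_POLICIES:
            raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
        object.__setattr__(self, "channels", tuple(self.channels))

    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels),
            "k": self.k,
            "ratio": self.ratio,
            "repeats": self.repeats,
            "threshold": self.threshold,
            "seed": self.seed,
            "missing_policy": self.missing_policy,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)  # YAML superset also parses JSON
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown config fields: {sorted(extra)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ("," if "," in line else None)


def _data_lines(path: str | Path) -> list[tuple[int, str]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            out.append((lineno, line))
    return out


_PAIR_HEADERS = {"drug1", "drug2", "drug_1", "drug_2", "drug_a", "drug_b",
                 "source", "target", "id1", "id2"}


def read_pair_list(path: str | Path, drugs: DrugSet | str = "infer") -> CombinationNetwork:
    """Read a two-column pair list into a :class:`CombinationNetwork`.

    Duplicate and reversed-duplicate rows collapse to a single edge. With
    ``drugs="infer"`` the universe is the sorted union of mentioned ids; with
    a fixed :class:`DrugSet`, unknown ids are an error.
    """
    lines = _data_lines(path)
    if not lines:
        raise ValueError(f"empty pair list: {path}")
    rows: list[tuple[str, str]] = []
    for pos, (lineno, line) in enumerate(lines):
        delim = _sniff_delimiter(line)
        fields = [f.strip() for f in (line.split(delim) if delim else line.split())]
        fields = [f for f in fields if f]
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        a, b = fields
        if pos == 0 and a.lower() in _PAIR_HEADERS and b.lower() in _PAIR_HEADERS:
            continue  # optional header row
        if a == b:
            raise ValueError(f"{path}:{lineno}: self-pair {a!r}")
        rows.append((a, b))
    if not rows:
        raise ValueError(f"pair list {path} has a header but no data rows")
    if isinstance(drugs, str):
        if drugs != "infer":
            raise ValueError('drugs must be a DrugSet or the string "infer"')
        universe = DrugSet(tuple(sorted({d for p in rows for d in p})))
    else:
        universe = drugs
        for a, b in rows:
            for d in (a, b):
                if d not in universe:
                    raise KeyError(f"{path}: drug id {d!r} not in the fixed DrugSet")
    return CombinationNetwork(universe, tuple(rows))


def write_pair_list(network: CombinationNetwork, path: str | Path,
                    header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for a, b in sorted(network.positive_pairs):
            fh.write(f"{a}\t{b}\n")


def read_profile(path: str | Path, channel: str) -> FeatureProfile:
    """Read a set-valued profile, auto-detecting long vs GMT-like layout.

    Long format: every row has exactly two columns ``drug<TAB>token``.
    GMT-like: ``drug<TAB>token1<TAB>token2...`` (token-less rows allowed and
    recorded as empty sets). The detected format is logged.
    """
    lines = _data_lines(path)
    if not lines:
        raise ValueError(f"empty profile file: {path}")
    rows = []
    for lineno, line in lines:
        fields = [f.strip() for f in line.split("\t")]
        fields = [f for f in fields if f]
        if fields:
            rows.append((lineno, fields))
    # a file where every row has exactly 2 fields is treated as long format
    is_long = all(len(f) == 2 for _, f in rows)
    members: dict[str, set[str]] = {}
    if is_long:
        logger.info("read_profile(%s): detected long format", path)
        seen_rows = set()
        for lineno, (drug, token) in rows:
            if (drug, token) in seen_rows:
                warnings.warn(f"{path}:{lineno}: duplicate row ({drug}, {token}); "
                              "set semantics keep one copy")
            seen_rows.add((drug, token))
            members.setdefault(drug, set()).add(token)
    else:
        logger.info("read_profile(%s): detected GMT-like format", path)
        for lineno, fields in rows:
            drug, tokens = fields[0], fields[1:]
            if drug in members:
                warnings.warn(f"{path}:{lineno}: duplicate drug row {drug!r}; merging")
            members.setdefault(drug, set()).update(tokens)
    return FeatureProfile(channel, {d: frozenset(t) for d, t in members.items()})


def write_profile(profile: FeatureProfile, path: str | Path) -> None:
    """Write GMT-like rows; drugs with empty sets emit a bare-id row."""
    with open(path, "w") as fh:
        for drug in sorted(profile.members):
            toks = sorted(profile.members[drug])
            fh.write("\t".join([drug, *toks]) + "\n")


def read_similarity_matrix(path: str | Path, channel: str = "similarity",
                           scale: str = "unit") -> SimilarityMatrix:
    """Read a square labeled similarity matrix (TSV or CSV).

    ``scale="percent"`` divides entries by 100 (e.g. 0-100 structure scores).
    The matrix is symmetrized by averaging; asymmetry beyond 1e-6 is an
    error, and a non-unit diagonal is forced to 1 with a warning.
    """
    import pandas as pd

    if scale not in ("unit", "percent"):
        raise ValueError('scale must be "unit" or "percent"')
    with open(path) as fh:
        first = fh.readline()
    delim = _sniff_delimiter(first) or "\t"
    df = pd.read_csv(path, sep=delim, index_col=0, comment="#")
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is {df.shape[0]}x{df.shape[1]}, not square")
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if rows != cols:
        if sorted(rows) != sorted(cols):
            raise ValueError(f"{path}: row and column labels differ")
        df = df.loc[rows, rows]
    v = df.to_numpy(dtype=float)
    if scale == "percent":
        v = v / 100.0
    asym = np.abs(v - v.T).max() if v.size else 0.0
    if asym > ASYMMETRY_TOL:
        i, j = np.unravel_index(np.argmax(np.abs(v - v.T)), v.shape)
        raise ValueError(
            f"{path}: asymmetry {asym:.3g} at ({rows[i]}, {rows[j]}) exceeds {ASYMMETRY_TOL}"
        )
    v = (v + v.T) / 2.0
    bad = (v < -1e-12) | (v > 1 + 1e-12)
    np.fill_diagonal(bad, False)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"{path}: entry {v[i, j]} outside [0,1] after scaling at ({rows[i]}, {cols[j]})"
        )
    diag = np.diag(v)
    if not np.allclose(diag, 1.0):
        warnings.warn(f"{path}: diagonal not 1 (min {diag.min():.3g}); forcing to 1")
    np.fill_diagonal(v, 1.0)
    return SimilarityMatrix(channel, DrugSet(tuple(rows)), v)


def write_similarity_matrix(matrix: SimilarityMatrix, path: str | Path,
                            header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        ids = matrix.drugs.ids
        fh.write("\t".join(["drug", *ids]) + "\n")
        for i, drug in enumerate(ids):
            row = "\t".join(repr(float(x)) for x in matrix.values[i])
            fh.write(f"{drug}\t{row}\n")


REPORT_COLUMNS = ("model", "k", "metric", "mean", "sd", "cell")


def format_cell(mean: float, sd: float) -> str:
    """Render an aggregated metric the way result tables print it."""
    return f"{mean:.3f} ± {sd:.3f}"


def write_report(report, path: str | Path) -> None:
    """Write an evaluation report as a TSV with one row per (model, k, metric).

    The ``cell`` column renders "mean ± sd" to 3 decimals; ``mean``/``sd``
    keep full precision so the file round-trips through
    :func:`read_report`.
    """
    with open(path, "w") as fh:
        fh.write(f"# seed={report.seed} config={report.config_hash}\n")
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for model, k, metric, mean, sd in report.iter_rows():
            fh.write(
                f"{model}\t{k}\t{metric}\t{mean!r}\t{sd!r}\t{format_cell(mean, sd)}\n"
            )


def read_report(path: str | Path):
    """Read a report written by :func:`write_report` back to aggregated form."""
    from .evaluation import EvaluationReport  # local import: avoids a cycle

    lines = _data_lines(path)
    if not lines or lines[0][1].split("\t")[:3] != ["model", "k", "metric"]:
        raise ValueError(f"{path}: not a report table")
    agg: dict[tuple[str, int], dict[str, tuple[float, float]]] = {}
    for _, line in lines[1:]:
        model, k, metric, mean, sd, _cell = line.split("\t")
        agg.setdefault((model, int(k)), {})[metric] = (float(mean), float(sd))
    return EvaluationReport.from_aggregates(agg)
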