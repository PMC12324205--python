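"""Canonical unordered protein-pair keys and pair-keyed table I/O.

Every pairwise quantity in the package is keyed by a canonical pair id:
the two accessions sorted lexicographically and joined by a single space.
Feature tables are pandas DataFrames indexed by that key; network files
use the ``pairsWprob`` dialect (``ID1<TAB>ID2<TAB>score``, no header).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import pandas as pd

PAIR_SEP = " "


def pair_key(a: str, b: str) -> str:
    """Canonical order-invariant key for an unordered protein pair."""
    a, b = str(a), str(b)
    if not a or not b:
        raise ValueError("protein ids must be nonempty")
    return f"{a}{PAIR_SEP}{b}" if a <= b else f"{b}{PAIR_SEP}{a}"


def split_pair_key(key: str) -> tuple[str, str]:
    a, sep, b = key.partition(PAIR_SEP)
    if not sep:
        raise ValueError(f"malformed pair key: {key!r}")
    return a, b


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a pair-keyed feature table as (optionally gzipped) CSV.

    First column is the canonical pair key; empty cells mean missing.
    Compression is inferred from a ``.gz`` suffix.
    """
    table = table.copy()
    table.index.name = "pair_id"
    table.to_csv(path)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="pair_id")
    return df


def write_pairs_wprob(scores: pd.Series, path: str | Path) -> None:
    """Write scores to pairsWprob: ``ID1<TAB>ID2<TAB>score``, no header.

    Rows are sorted by descending score with ties broken by pair key so
    exports are byte-stable.
    """
    ordered = scores.sort_index().sort_values(ascending=False, kind="stable")
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for key, score in ordered.items():
            a, b = split_pair_key(str(key))
            fh.write(f"{a}\t{b}\t{score:.17g}\n")


def read_pairs_wprob(path: str | Path) -> pd.Series:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    keys: list[str] = []
    vals: list[float] = []
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            a, b, s = line.split("\t")
            keys.append(pair_key(a, b))
            vals.append(float(s))
    return pd.Series(vals, index=keys, name="score")


def all_pairs(ids: Iterable[str]) -> set[str]:
    """All canonical pair keys over a set of protein ids."""
    ids = sorted(set(map(str, ids)))
    return {pair_key(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]}
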