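"""Bundled example datasets.

``load_toy``
    The nine-compound illustrative series on the scaffold
    {A,B,C,D} x {A,B,C,D} x {A,B,C} (three of interest).
``load_antihiv``
    132 anti-HIV nucleoside analogues over a nine-site scaffold, split into
    a 61-compound training set (TRN, 21 active) and two external sets
    (Ex1: 56 compounds, 12 active; Ex2: 15 compounds, 2 active).  The one
    duplicated compound of the source data is already removed.
"""

from __future__ import annotations

from importlib import resources

from .scaffold import Dataset, load_dataset, parse_scaffold

__all__ = ["load_toy", "load_antihiv"]


def _load(scaffold_file: str, table_file: str) -> Dataset:
    pkg = resources.files("ssir.data")
    scaffold = parse_scaffold((pkg / scaffold_file).read_text())
    with (pkg / table_file).open() as fh:
        return load_dataset(fh, scaffold)


def load_toy() -> Dataset:
    """Nine labelled compounds on the three-site toy scaffold."""
    return _load("toy_scaffold.json", "toy.tsv")


def load_antihiv() -> Dataset:
    """All 132 anti-HIV analogues; filter with ``.subset("TRN"|"Ex1"|"Ex2")``."""
    return _load("antihiv_scaffold.json", "antihiv.tsv")
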