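"""Scaffolds, compounds and labelled datasets for combinatorial analogue series.

A combinatorial series is described by a common molecular scaffold with an
ordered list of substitution sites.  Each site carries a finite alphabet of
residue tokens; a compound is one token per site.  Tokens are opaque symbols:
the same letter at two different sites denotes different chemistry and is
never compared across sites.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "Site",
    "Scaffold",
    "Compound",
    "Dataset",
    "CombinatoricsSummary",
    "parse_scaffold",
    "parse_compound",
    "load_dataset",
    "observed_alphabets",
    "combinatorics",
    "ScaffoldFormatError",
    "CompoundValidationError",
]

_TRUE_LABELS = {"+1", "1", "Y", "y", "yes", "true", "True"}
_FALSE_LABELS = {"-1", "−1", "N", "n", "no", "false", "False"}


class ScaffoldFormatError(ValueError):
    """Malformed scaffold configuration."""


class CompoundValidationError(ValueError):
    """Compound code inconsistent with its scaffold."""


@dataclass(frozen=True)
class Site:
    name: str
    alphabet: tuple[str, ...]

    def __post_init__(self):
        if len(self.alphabet) == 0:
            raise ScaffoldFormatError(f"site {self.name!r} has an empty alphabet")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ScaffoldFormatError(f"site {self.name!r} has duplicate residue tokens")

    @property
    def m(self) -> int:
        """Alphabet size of the site."""
        return len(self.alphabet)


@dataclass(frozen=True)
class Scaffold:
    """Ordered substitution sites, each with a residue alphabet."""

    sites: tuple[Site, ...]
    name: str = "scaffold"

    def __post_init__(self):
        if len(self.sites) == 0:
            raise ScaffoldFormatError("a scaffold needs at least one site")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def m(self) -> tuple[int, ...]:
        """Per-site alphabet sizes (m_1, ..., m_s)."""
        return tuple(site.m for site in self.sites)

    def alphabets(self) -> tuple[tuple[str, ...], ...]:
        return tuple(site.alphabet for site in self.sites)

    def single_char(self) -> bool:
        """True when every residue token is one character (compact code mode)."""
        return all(len(t) == 1 for site in self.sites for t in site.alphabet)

    def parse_code(self, text: str, delimiter: Optional[str] = None) -> tuple[str, ...]:
        """Split a code string into one token per site and validate it."""
        if delimiter is not None:
            tokens = tuple(text.split(delimiter))
        elif self.single_char():
            tokens = tuple(text)
        else:
            tokens = tuple(text.split("-"))
        if len(tokens) != self.n_sites:
            raise CompoundValidationError(
                f"code {text!r} has {len(tokens)} tokens, scaffold has {self.n_sites} sites"
            )
        for k, (tok, site) in enumerate(zip(tokens, self.sites), start=1):
            if tok not in site.alphabet:
                raise CompoundValidationError(
                    f"token {tok!r} not in the alphabet of site {k} ({site.name})"
                )
        return tokens

    def render_code(self, code: Sequence[str], delimiter: Optional[str] = None) -> str:
        if delimiter is not None:
            return delimiter.join(code)
        if self.single_char():
            return "".join(code)
        return "-".join(code)


@dataclass(frozen=True)
class Compound:
    """A single analogue: one residue token per scaffold site."""

    id: str
    code: tuple[str, ...]
    label: Optional[bool] = None  # True = of interest / active
    subset: Optional[str] = None


@dataclass
class Dataset:
    """Labelled compounds over a common scaffold.

    ``L`` is the library size and ``I`` the number of compounds of interest;
    the hypergeometric significance of every rule is computed against these
    two counts.
    """

    scaffold: Scaffold
    compounds: list[Compound] = field(default_factory=list)

    def __post_init__(self):
        ids = [c.id for c in self.compounds]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate compound ids: {dup}")
        for c in self.compounds:
            if len(c.code) != self.scaffold.n_sites:
                raise CompoundValidationError(
                    f"compound {c.id}: code length {len(c.code)} != {self.scaffold.n_sites} sites"
                )

    @property
    def L(self) -> int:
        return len(self.compounds)

    @property
    def I(self) -> int:  # noqa: E743 - field name from the method's notation
        return sum(1 for c in self.compounds if c.label)

    def labels(self) -> list[Optional[bool]]:
        return [c.label for c in self.compounds]

    def codes(self) -> list[tuple[str, ...]]:
        return [c.code for c in self.compounds]

    def subset(self, tag: Union[str, Iterable[str]]) -> "Dataset":
        tags = {tag} if isinstance(tag, str) else set(tag)
        return Dataset(self.scaffold, [c for c in self.compounds if c.subset in tags])

    def __len__(self) -> int:
        return self.L

    def __iter__(self):
        return iter(self.compounds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [c.id for c in self.compounds],
                "code": [self.scaffold.render_code(c.code) for c in self.compounds],
                "label": [c.label for c in self.compounds],
                "subset": [c.subset for c in self.compounds],
            }
        )


@dataclass(frozen=True)
class CombinatoricsSummary:
    """Sizes of the combinatorial space and of the definable rule universe."""

    M: int
    per_site_term_counts: tuple[int, ...]
    R: int


def parse_scaffold(config: Union[str, Path, dict]) -> Scaffold:
    """Build a :class:`Scaffold` from a JSON file, JSON text, or a dict.

    The expected structure is ``{"name": ..., "sites": [{"name": ...,
    "residues": [...]}, ...]}``.
    """
    if isinstance(config, Path) or (isinstance(config, str) and not config.lstrip().startswith("{")):
        with open(config) as fh:
            obj = json.load(fh)
    elif isinstance(config, str):
        obj = json.loads(config)
    else:
        obj = config
    if not obj.get("sites"):
        raise ScaffoldFormatError("scaffold config lists no sites")
    sites = []
    for k, rec in enumerate(obj["sites"], start=1):
        sites.append(Site(rec.get("name", f"site{k}"), tuple(rec["residues"])))
    return Scaffold(tuple(sites), name=obj.get("name", "scaffold"))


def parse_compound(
    code_text: str,
    scaffold: Scaffold,
    id: Optional[str] = None,
    label: Optional[bool] = None,
    subset: Optional[str] = None,
    delimiter: Optional[str] = None,
) -> Compound:
    """Parse a symbolic code like ``"ACB"`` into a validated :class:`Compound`."""
    code = scaffold.parse_code(code_text, delimiter=delimiter)
    return Compound(id if id is not None else code_text, code, label, subset)


def _parse_label(raw) -> Optional[bool]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text in _TRUE_LABELS:
        return True
    if text in _FALSE_LABELS:
        return False
    raise ValueError(f"unparseable activity label {raw!r} (expected +1/-1 or Y/N)")


def load_dataset(table, scaffold: Scaffold, delimiter: Optional[str] = None) -> Dataset:
    """Load a TSV with columns ``id  code  label  [subset]`` into a Dataset."""
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table, sep="\t", dtype=str)
    if "id" not in df.columns or "code" not in df.columns:
        raise ValueError("dataset table needs 'id' and 'code' columns")
    compounds = []
    for _, row in df.iterrows():
        compounds.append(
            parse_compound(
                row["code"],
                scaffold,
                id=str(row["id"]),
                label=_parse_label(row.get("label")),
                subset=(str(row["subset"]) if "subset" in df.columns and pd.notna(row["subset"]) else None),
                delimiter=delimiter,
            )
        )
    ds = Dataset(scaffold, compounds)
    # Duplicate codes inside one subset usually indicate a transcription slip
    # (the method itself tolerates replicates), so warn rather than fail.
    seen: dict[tuple, str] = {}
    for c in ds.compounds:
        key = (c.subset, c.code)
        if key in seen:
            warnings.warn(
                f"compounds {seen[key]} and {c.id} share code "
                f"{scaffold.render_code(c.code)} within subset {c.subset}"
            )
        seen[key] = c.id
    return ds


def observed_alphabets(dataset: Dataset) -> tuple[tuple[str, ...], ...]:
    """Per-site residues occurring in at least one compound, in scaffold order."""
    if dataset.L == 0:
        raise ValueError("cannot derive observed alphabets from an empty dataset")
    out = []
    for k, site in enumerate(dataset.scaffold.sites):
        present = {c.code[k] for c in dataset.compounds}
        out.append(tuple(t for t in site.alphabet if t in present))
    return tuple(out)


def combinatorics(
    scaffold: Scaffold,
    universe: str = "full",
    dataset: Optional[Dataset] = None,
    max_level: Optional[int] = None,
) -> CombinatoricsSummary:
    """Combinatorial sizes: library size ``M``, per-site term counts, total rules ``R``.

    ``M`` is the product of the site alphabet sizes.  With the exhaustive term
    level (``max_level=None`` means level up to ``m_i - 1`` at each site) the
    total number of definable rules of any order is
    ``R = prod(2**m_i - 1) - 1``: each factor counts all non-empty residue
    subsets at a site (the full subset playing the role of the wildcard) and
    the final unit removes the order-0 all-wildcard rule.
    """
    from .rules import count_terms  # local import to avoid a cycle

    if universe == "observed":
        if dataset is None:
            raise ValueError("universe='observed' requires a dataset")
        alphabets = observed_alphabets(dataset)
    elif universe == "full":
        alphabets = scaffold.alphabets()
    else:
        raise ValueError(f"unknown universe {universe!r}")
    m_full = scaffold.m
    M = math.prod(m_full)
    sizes = tuple(len(a) for a in alphabets)
    levels = [m - 1 if max_level is None else min(max_level, m - 1) for m in sizes]
    term_counts = tuple(count_terms(m, lvl) for m, lvl in zip(sizes, levels))
    R = math.prod(t + 1 for t in term_counts) - 1
    return CombinatoricsSummary(M=M, per_site_term_counts=term_counts, R=R)
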