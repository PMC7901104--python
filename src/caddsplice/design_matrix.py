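"""Expansion of annotated variants into the model's dense feature matrix.

The matrix concatenates five column groups:

* ``X`` — numeric annotations (missing imputed to 0) and one-hot encoded
  categorical annotations, including the variant consequence;
* ``base_pairs`` — the 12 ordered nucleotide substitution indicators (i != j);
* ``aa_exchange`` — indicators over the amino-acid exchanges reachable by a
  single-nucleotide codon change (189 under the standard genetic code,
  including the synonymous self-exchanges that a codon change can produce);
* ``W`` — Boolean missingness indicators, one per configured feature group;
* ``interactions`` — consequence x annotation products over the designated
  interaction set ``D``, giving each consequence category its own slope for
  those annotations.

With the shipped default schema the groups have sizes 222 / 12 / 189 / 14 /
592 for 1029 columns in total.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .core_model import (
    MISSING,
    AA_ALPHABET,
    NUCLEOTIDES,
    AnnotatedVariant,
    FeatureSchema,
    is_missing,
)

__all__ = [
    "DesignMatrix",
    "enumerate_base_pairs",
    "enumerate_aa_exchanges",
    "encode_variant",
    "build_matrix",
]


def enumerate_base_pairs() -> list[tuple[str, str]]:
    """All ordered (ref, alt) nucleotide pairs with ref != alt, in canonical
    row-major A/C/G/T order. Always 12 pairs."""
    return [(r, a) for r in NUCLEOTIDES for a in NUCLEOTIDES if r != a]


_BASE_PAIR_INDEX = {p: i for i, p in enumerate(enumerate_base_pairs())}
_AA_EXCHANGES: list[tuple[str, str]] | None = None
_AA_INDEX: dict[tuple[str, str], int] = {}


def _aa_exchange_index() -> dict[tuple[str, str], int]:
    global _AA_EXCHANGES, _AA_INDEX
    if _AA_EXCHANGES is None:
        _AA_EXCHANGES = enumerate_aa_exchanges()
        _AA_INDEX = {p: i for i, p in enumerate(_AA_EXCHANGES)}
    return _AA_INDEX


def _translate(codon: str, forward: dict, stops: frozenset) -> str:
    return "*" if codon in stops else forward[codon]


def enumerate_aa_exchanges(genetic_code=None) -> list[tuple[str, str]]:
    """Amino-acid exchanges creatable by mutating one base of any codon.

    Brute force over all 64 codons x 9 single-base mutants under the standard
    genetic code (alphabet: 20 amino acids + stop). A pair (ref, alt) is
    included whenever some codon change produces it — including synonymous
    self-pairs (ref, ref), which exist for 19 of the 21 symbols (neither Met
    nor Trp has a synonymous single-base change). This yields 189 distinct
    ordered pairs: 170 with ref != alt plus 19 self-pairs.

    Order is deterministic: alphabet order of ref, then of alt, with the stop
    symbol last.
    """
    table = genetic_code if genetic_code is not None else standard_dna_table
    forward = table.forward_table
    stops = frozenset(table.stop_codons)
    codons = [a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES]
    pairs: set[tuple[str, str]] = set()
    for codon in codons:
        ref_aa = _translate(codon, forward, stops)
        for i in range(3):
            for base in NUCLEOTIDES:
                if base == codon[i]:
                    continue
                mutant = codon[:i] + base + codon[i + 1:]
                alt_aa = _translate(mutant, forward, stops)
                pairs.add((ref_aa, alt_aa))
    index = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    return sorted(pairs, key=lambda p: (index[p[0]], index[p[1]]))


@dataclass
class DesignMatrix:
    """Dense feature matrix plus its column bookkeeping.

    ``column_groups`` partitions the ordered ``columns`` into the five groups
    (name -> list of column names); ``values`` has one row per input variant,
    in input order.
    """

    columns: list[str]
    values: np.ndarray
    column_groups: dict[str, list[str]]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def group_slice(self, group: str) -> slice:
        start = 0
        for name, cols in self.column_groups.items():
            if name == group:
                return slice(start, start + len(cols))
            start += len(cols)
        raise KeyError(group)

    def to_tsv(self, path) -> None:
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            fh.write("\t".join(self.columns) + "\n")
            for row in self.values:
                fh.write("\t".join(format(v, "g") for v in row) + "\n")

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"columns": self.columns, "column_groups": self.column_groups},
                fh, indent=1,
            )

    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            values=self.values,
            columns=np.asarray(self.columns),
            groups_json=np.asarray(json.dumps(self.column_groups)),
        )

    @classmethod
    def load_npz(cls, path) -> "DesignMatrix":
        data = np.load(path, allow_pickle=False)
        return cls(
            columns=[str(c) for c in data["columns"]],
            values=data["values"],
            column_groups=json.loads(str(data["groups_json"])),
        )


def _column_layout(schema: FeatureSchema):
    x_cols: list[str] = list(schema.numeric_annotation_names)
    for name, levels in schema.categorical_annotations.items():
        x_cols.extend(f"{name}={level}" for level in levels)
    bp_cols = [f"sub:{r}>{a}" for r, a in enumerate_base_pairs()]
    aa_cols = [f"aa:{r}>{a}" for r, a in enumerate_aa_exchanges()]
    w_cols = [f"W:{name}" for name in schema.indicator_names]
    ix_cols = [
        f"ix:{cons}*{d}"
        for cons in schema.consequence_categories
        for d in schema.interaction_set
    ]
    return {
        "X": x_cols,
        "base_pairs": bp_cols,
        "aa_exchange": aa_cols,
        "W": w_cols,
        "interactions": ix_cols,
    }


def _annotation_value(av: AnnotatedVariant, name: str, schema: FeatureSchema):
    if name == "Consequence":
        return av.consequence
    if name in schema.categorical_annotations:
        return av.categorical_annotations.get(name, MISSING)
    if name == "aa_exchange":
        return av.aa_exchange if av.aa_exchange is not None else MISSING
    return av.numeric_annotations.get(name, MISSING)


def encode_variant(
    av: AnnotatedVariant, schema: FeatureSchema, _layout=None
) -> np.ndarray:
    """Encode one annotated variant as a dense feature row.

    Missing numeric values impute to 0 with the covering ``W`` indicator set;
    missing categoricals encode as an all-zero one-hot group. The interaction
    block copies the (imputed) interaction-set values into the slice belonging
    to the variant's consequence and is zero elsewhere.
    """
    for name in av.numeric_annotations:
        if name not in schema.numeric_annotation_names:
            raise KeyError(f"numeric annotation {name!r} not in schema")
    for name in av.categorical_annotations:
        if name not in schema.categorical_annotations:
            raise KeyError(f"categorical annotation {name!r} not in schema")
    if av.consequence not in schema.consequence_categories:
        raise ValueError(f"unknown consequence {av.consequence!r}")
    if av.aa_exchange is not None and av.consequence not in schema.coding_consequences:
        raise ValueError(
            f"aa_exchange set on non-coding consequence {av.consequence!r}"
        )

    layout = _layout if _layout is not None else _column_layout(schema)
    row = np.zeros(sum(len(v) for v in layout.values()))
    offset = 0

    # X block: numerics then categorical one-hots
    imputed: dict[str, float] = {}
    for i, name in enumerate(schema.numeric_annotation_names):
        value = av.numeric_annotations.get(name, MISSING)
        x = 0.0 if is_missing(value) else float(value)
        imputed[name] = x
        row[offset + i] = x
    pos = offset + len(schema.numeric_annotation_names)
    for name, levels in schema.categorical_annotations.items():
        value = av.consequence if name == "Consequence" \
            else av.categorical_annotations.get(name, MISSING)
        if not is_missing(value):
            if value not in levels:
                raise ValueError(f"{name}={value!r} not a configured level")
            row[pos + levels.index(value)] = 1.0
        pos += len(levels)
    offset += len(layout["X"])

    # base-substitution indicators (SNVs only)
    if av.variant.is_snv:
        pair = (av.variant.ref, av.variant.alt)
        row[offset + _BASE_PAIR_INDEX[pair]] = 1.0
    offset += len(layout["base_pairs"])

    # amino-acid exchange indicator
    if av.aa_exchange is not None:
        aa_index = _aa_exchange_index()
        pair = tuple(av.aa_exchange)
        if pair not in aa_index:
            raise ValueError(
                f"aa exchange {av.aa_exchange} not reachable by a single"
                " nucleotide change"
            )
        row[offset + aa_index[pair]] = 1.0
    offset += len(layout["aa_exchange"])

    # W missingness indicators: set when the whole covered group is undefined
    for i, indicator in enumerate(schema.indicator_names):
        group = schema.indicator_groups.get(indicator, (indicator,))
        if all(is_missing(_annotation_value(av, name, schema)) for name in group):
            row[offset + i] = 1.0
    offset += len(layout["W"])

    # consequence x D interactions
    cons_idx = schema.consequence_categories.index(av.consequence)
    d_size = len(schema.interaction_set)
    for j, d_name in enumerate(schema.interaction_set):
        row[offset + cons_idx * d_size + j] = imputed.get(d_name, 0.0)

    return row


def build_matrix(
    variants: Sequence[AnnotatedVariant], schema: FeatureSchema
) -> DesignMatrix:
    """Stack encoded rows for a variant list, preserving input order."""
    if len(variants) == 0:
        raise ValueError("cannot build a design matrix from an empty variant list")
    layout = _column_layout(schema)
    columns = [c for cols in layout.values() for c in cols]
    values = np.vstack(
        [encode_variant(v, schema, _layout=layout) for v in variants]
    )
    return DesignMatrix(columns=columns, values=values, column_groups=layout)
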