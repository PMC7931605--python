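"""Shared genotype codes and exception types.

Genotypes are encoded as small integers throughout the package:

* ``AA`` (0)  — homozygous for the female-parent allele,
* ``AB`` (1)  — heterozygous,
* ``BB`` (2)  — homozygous for the male-parent allele,
* ``UNKNOWN`` (-1) — missing / undecodable.

Single-letter codes used in text exports mirror common bin-map
conventions: A / H / B / U.
"""

from __future__ import annotations

AA: int = 0
AB: int = 1
BB: int = 2
UNKNOWN: int = -1

GENOTYPE_LETTER = {AA: "A", AB: "H", BB: "B", UNKNOWN: "U"}
LETTER_GENOTYPE = {v: k for k, v in GENOTYPE_LETTER.items()}

#: genotype code -> additive dosage x (+1 female-hom, 0 het, -1 male-hom)
ADDITIVE_CODE = {AA: 1.0, AB: 0.0, BB: -1.0}
#: genotype code -> dominance indicator z (1 iff heterozygous)
DOMINANCE_CODE = {AA: 0.0, AB: 1.0, BB: 0.0}


class BinqtlError(Exception):
    """Base class for package errors."""


class ConfigError(BinqtlError):
    """Invalid configuration or parameter value."""


class InputError(BinqtlError):
    """Malformed or inconsistent input data."""


class DependencyError(BinqtlError):
    """A pipeline stage was requested before the stage it depends on."""
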