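"""Small shared helpers: half-up rounding, genotype normalization, seeding."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, matching how printed percentages round.

    Python's built-in round() is banker's rounding; reported figures such as
    a concordance of 98.7% use ordinary half-up rounding.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def norm_genotype(*alleles: str) -> tuple[str, ...]:
    """Canonical unordered genotype: uppercase alleles, sorted (A/G == G/A)."""
    return tuple(sorted(a.upper() for a in alleles))


def genotype_key(gt) -> str:
    """String key for a genotype, e.g. ('G','A') -> 'AG'."""
    if isinstance(gt, str):
        gt = gt.replace("/", "").replace("|", "")
        return "".join(sorted(gt.upper()))
    return "".join(norm_genotype(*gt))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def rng_from_seed(seed: int, stream: str = "") -> np.random.Generator:
    """One named generator per logical stream, all derived from one seed."""
    ss = np.random.SeedSequence([seed, *(ord(c) for c in stream)])
    return np.random.default_rng(ss)
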