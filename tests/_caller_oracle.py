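"""Independent brute-force re-statement of the heteroplasmy criteria.

Written directly from the verbal definition — a site is a variant when the
gated coverage is high enough, there is only one alternative nucleotide, the
alternative shows up in enough reads with at least one on each strand, the
alternative bases are far from the read ends and the supporting reads'
neighborhoods are error-free. Used only as a test oracle; deliberately
naive and separate from the package implementation.
"""

from __future__ import annotations

import numpy as np


def oracle_accepts(col, params, context=None):
    """Return the accepted alt base, or None."""
    gated = []
    for o in col.observations:
        if o.is_deletion or o.base == "N":
            continue
        if o.base_quality < params.min_base_quality:
            continue
        if o.mapping_quality is not None and o.mapping_quality < params.min_mapping_quality:
            continue
        gated.append(o)
    if len(gated) < params.min_coverage:
        return None
    alts = sorted({o.base for o in gated if o.base != col.ref_base})
    if len(alts) != 1:
        return None
    alt = alts[0]

    def far(o):
        if o.dist_to_5prime is None or o.dist_to_3prime is None:
            return True
        return min(o.dist_to_5prime, o.dist_to_3prime) >= params.min_read_end_distance

    def clean(o):
        if context is None or o.read_id is None:
            return True
        for q in range(col.position - params.neighborhood_window,
                       col.position + params.neighborhood_window + 1):
            if q == col.position or q not in context:
                continue
            other_col = context[q]
            for other in other_col.observations:
                if other.read_id == o.read_id:
                    if not other.is_deletion and other.base != other_col.ref_base:
                        return False
                    break
        return True

    support = [o for o in gated if o.base == alt and far(o) and clean(o)]
    if len(support) < params.min_alt_reads:
        return None
    strands = {o.strand for o in support}
    if params.require_both_strands and strands != {"forward", "reverse"}:
        return None
    return alt


def fuzz_column(rng: np.random.Generator, max_reads: int = 50):
    """A random pileup column exercising every gate of the cascade."""
    from mitoasym.hetcall import PileupColumn, ReadObservation

    bases = "ACGT"
    ref = bases[rng.integers(4)]
    favored_alt = rng.choice([b for b in bases if b != ref])
    n = int(rng.integers(1, max_reads + 1))
    obs = []
    for i in range(n):
        r = rng.random()
        if r < 0.65:
            base = ref
        elif r < 0.85:
            base = favored_alt  # biased so single-alt columns are common
        elif r < 0.95:
            base = bases[rng.integers(4)]
        else:
            base = "N"
        known_dist = rng.random() < 0.8
        obs.append(ReadObservation(
            base=base,
            strand="forward" if rng.random() < 0.5 else "reverse",
            base_quality=int(rng.integers(20, 46)),
            mapping_quality=int(rng.integers(20, 61)) if rng.random() < 0.8 else None,
            dist_to_5prime=int(rng.integers(0, 40)) if known_dist else None,
            dist_to_3prime=int(rng.integers(0, 40)) if known_dist else None,
            read_id=i,
            is_deletion=rng.random() < 0.03,
        ))
    return PileupColumn(position=int(rng.integers(1, 10_000)), ref_base=ref, observations=obs)
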