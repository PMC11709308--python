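"""Independent brute-force reference implementations used by the tests.

These deliberately avoid the package's matching and counting code paths:
claims are matched by set membership over pre-expanded code lists plus a
last-character suffix check, and combinations are enumerated over the full
powerset.  They exist so the pipeline can be checked against a second,
independently written route.
"""

import random

from fpscope.ingest import ClaimRecord


def oracle_tally(claims, registry):
    """Single-pass per-claim tally: expanded-set membership, then suffix."""
    code_sets = {s.service_id: set(s.iter_codes()) for s in registry.services}
    suffix_owner = {suf: s.service_id
                    for s in registry.services for suf in s.suffix_rules}
    counts, unclassified = {}, {}
    for c in claims:
        owner = None
        for sid, codes in code_sets.items():
            if c.fee_code in codes:
                owner = sid
                break
        if owner is None:
            owner = suffix_owner.get(c.fee_code[-1])
        if owner is None:
            unclassified[c.physician_id] = unclassified.get(c.physician_id, 0) + c.n_events
        else:
            per = counts.setdefault(c.physician_id, {})
            per[owner] = per.get(owner, 0) + c.n_events
    return counts, unclassified


def random_claims(registry, rng: random.Random, n_physicians: int, max_claims: int):
    """Random claim sets mixing sentinel, range, suffix-B and noise codes."""
    universe = sorted(registry.code_universe())
    pool = universe + ["Q999", "X123", "S727B", "Z999B", "A999"]
    claims = []
    for i in range(n_physicians):
        for _ in range(rng.randrange(max_claims + 1)):
            claims.append(ClaimRecord(
                f"P{i}", rng.choice(pool), 2017, n_events=rng.randrange(1, 4)
            ))
    return claims
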