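"""USPS state codes and stylized default population weights.

``STATE_CODES`` is the set of geographic units the package accepts:
the 50 states, the District of Columbia, and the national aggregate "US".

``DEFAULT_STATE_WEIGHTS`` gives each state-level unit a relative weight
roughly proportional to its share of the national population around the
1990 decennial census (coarse, to one part in a thousand). The synthetic
generator uses these as allocation probabilities; they are stylized
defaults, not fitted estimates.
"""

from __future__ import annotations

US = "US"

DEFAULT_STATE_WEIGHTS: dict[str, float] = {
    "AL": 1.6, "AK": 0.2, "AZ": 1.5, "AR": 0.9, "CA": 12.0,
    "CO": 1.3, "CT": 1.3, "DE": 0.3, "DC": 0.2, "FL": 5.2,
    "GA": 2.6, "HI": 0.4, "ID": 0.4, "IL": 4.6, "IN": 2.2,
    "IA": 1.1, "KS": 1.0, "KY": 1.5, "LA": 1.7, "ME": 0.5,
    "MD": 1.9, "MA": 2.4, "MI": 3.7, "MN": 1.8, "MS": 1.0,
    "MO": 2.1, "MT": 0.3, "NE": 0.6, "NV": 0.5, "NH": 0.4,
    "NJ": 3.1, "NM": 0.6, "NY": 7.2, "NC": 2.7, "ND": 0.3,
    "OH": 4.4, "OK": 1.3, "OR": 1.1, "PA": 4.8, "RI": 0.4,
    "SC": 1.4, "SD": 0.3, "TN": 2.0, "TX": 6.8, "UT": 0.7,
    "VT": 0.2, "VA": 2.5, "WA": 2.0, "WV": 0.7, "WI": 2.0,
    "WY": 0.2,
}

STATE_CODES: frozenset[str] = frozenset(DEFAULT_STATE_WEIGHTS) | {US}
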