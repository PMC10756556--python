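"""Inter-limb asymmetry index on daily parameter means.

The index compares the operated (ipsilateral) side with the contralateral side
within a girdle::

    asymmetry(%) = 100 * |X_I - X_C| / (0.5 * (X_I + X_C))

where X_I and X_C are the daily mean values of a gait parameter for the two
limbs.  Normalizing by the pair mean makes the index scale-free and symmetric:
0 for a perfectly symmetric gait, 200 when one limb bears nothing.  Values above
100 are possible (and observed post-operatively for the impulse), which is why
the pair-mean denominator — standard in the lameness literature — is used rather
than a max-normalized form.
"""

from __future__ import annotations

import logging

import pandas as pd

from .errors import UndefinedAsymmetryError, ValidationError

logger = logging.getLogger(__name__)

#: Limb pairs compared, per girdle: (ipsilateral, contralateral).
PAIRS = {"hind": ("IH", "CH"), "fore": ("IF", "CF")}


def asymmetry_index(x_ipsi: float, x_contra: float) -> float:
    """Pair-mean-normalized absolute asymmetry, in percent (range [0, 200])."""
    if x_ipsi < 0 or x_contra < 0:
        raise ValidationError("asymmetry inputs must be non-negative")
    total = x_ipsi + x_contra
    if total == 0:
        raise UndefinedAsymmetryError("asymmetry undefined: both limb values are zero")
    # algebraically 100*|d|/(0.5*s); clipped to guard the bound against round-off
    return min(200.0 * abs(x_ipsi - x_contra) / total, 200.0)


def asymmetry_series(
    daily: pd.DataFrame, parameter: str, pairs: dict[str, tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Per-animal, per-day asymmetry records for hind and fore limb pairs.

    ``daily`` is the long-format daily summary table.  Days missing either limb
    of a pair are skipped with a logged note; zero-denominator days are emitted
    with ``asymmetry_pct = NaN`` rather than dropped silently.
    """
    pairs = pairs or PAIRS
    sub = daily[daily["parameter"] == parameter]
    wide = sub.pivot_table(
        index=["animal_id", "day_postop"], columns="limb", values="mean", aggfunc="first"
    )
    rows = []
    for (animal, day), limb_means in wide.iterrows():
        for pair_name, (ipsi, contra) in pairs.items():
            x_i = limb_means.get(ipsi)
            x_c = limb_means.get(contra)
            if x_i is None or x_c is None or pd.isna(x_i) or pd.isna(x_c):
                logger.info(
                    "skipping %s pair for %s day %s: missing limb mean", pair_name, animal, day
                )
                continue
            try:
                value = asymmetry_index(float(x_i), float(x_c))
            except UndefinedAsymmetryError:
                value = float("nan")
            rows.append(
                {
                    "animal_id": animal,
                    "day_postop": day,
                    "pair": pair_name,
                    "parameter": parameter,
                    "x_ipsi": float(x_i),
                    "x_contra": float(x_c),
                    "asymmetry_pct": value,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["animal_id", "day_postop", "pair", "parameter", "x_ipsi", "x_contra", "asymmetry_pct"],
    )
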