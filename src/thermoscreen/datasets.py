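"""Published measurements from the thermotolerance study, as fixture inputs.

These are the small tables printed in the original report on thermotolerance-
correlated gene expression in *Saccharomyces cerevisiae* (strains NFRI 3236 /
S288C / NFRI 3155): microarray fold changes of the three candidate genes,
doubling times at 30°C and 39°C, and qPCR expression ratios of *FMP21*.  They
are inputs for worked examples and concordance checks — the raw arrays and
growth traces behind them were never published, so quantities like the full
441-gene stage-1 list cannot be recomputed from these tables alone.
"""

from __future__ import annotations

import pandas as pd

from .growth import DoublingTimeResult, TdRatio, td_ratio
from .screen import FoldChangeTable

__all__ = [
    "TOLERANT",
    "REFERENCE",
    "SENSITIVE",
    "STRAIN_ROLES",
    "candidate_fold_changes",
    "published_doubling_times",
    "published_td_ratios",
    "published_qpcr_ratios",
]

TOLERANT = "NFRI3236"
REFERENCE = "S288C"
SENSITIVE = "NFRI3155"

STRAIN_ROLES = {
    "tolerant": TOLERANT,
    "reference": REFERENCE,
    "sensitive": SENSITIVE,
}

# candidate-gene fold changes (heat 39°C / control) per strain
_FOLD_CHANGES = {
    "FMP21": {TOLERANT: 3.68, REFERENCE: 2.18, SENSITIVE: 1.35},
    "YER034W": {TOLERANT: 3.10, REFERENCE: 1.51, SENSITIVE: 0.49},
    "PRM5": {TOLERANT: 48.21, REFERENCE: 23.05, SENSITIVE: 15.07},
}

# doubling times in hours: {strain: {temperature: T_d}}
_DOUBLING_TIMES = {
    TOLERANT: {"30C": 1.15, "39C": 1.75},
    SENSITIVE: {"30C": 1.28, "39C": 2.90},
    REFERENCE: {"30C": 1.34, "39C": 2.11},
}

# FMP21 heat/control expression ratios from the qPCR verification
_QPCR_RATIOS = {TOLERANT: 8.50, REFERENCE: 4.50, SENSITIVE: 3.47}


def candidate_fold_changes() -> FoldChangeTable:
    """Fold-change table of the three candidate genes in the three strains."""
    return FoldChangeTable(folds=pd.DataFrame(_FOLD_CHANGES).T)


def published_doubling_times() -> dict[str, dict[str, DoublingTimeResult]]:
    """Printed doubling times as results keyed strain -> temperature.

    The window and fit quality of the original estimates were not reported;
    both are set to placeholder values here.
    """
    return {
        strain: {
            temp: DoublingTimeResult(
                strain=strain, temperature=temp, td=td,
                window=(0, 1), fit_quality=1.0,
            )
            for temp, td in temps.items()
        }
        for strain, temps in _DOUBLING_TIMES.items()
    }


def published_td_ratios() -> list[TdRatio]:
    """T_d(30°C)/T_d(39°C) per strain, computed from the printed values."""
    tds = published_doubling_times()
    return [td_ratio(tds[s]["30C"], tds[s]["39C"]) for s in tds]


def published_qpcr_ratios() -> dict[str, float]:
    """FMP21 heat/control expression ratios per strain (qPCR, reference ACT1)."""
    return dict(_QPCR_RATIOS)
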