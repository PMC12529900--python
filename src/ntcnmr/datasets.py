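"""Published per-phosphate NMR observables of the Dickerson-Drew dodecamer.

Two small literature-derived tables ship with the package, one value per
internucleotide step (11 rows each), all internally referenced to the
A6pT7 phosphate:

``dickerson_drew_shifts``
    delta-31P chemical shifts (ppm): ensemble averages calculated over
    X-ray and over NMR solution structures of the duplex, alongside the
    measured values (phosphate buffer, pH 7.0, 20 degC).

``dickerson_drew_couplings``
    3J(P,H3') couplings (Hz): the same two calculated columns alongside
    the averaged measured couplings.

These serve as reference inputs for the deviation metric and as worked
examples; they are compiled published values, not outputs of this package.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["dickerson_drew_shifts", "dickerson_drew_couplings"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("ntcnmr").joinpath("data", name).open() as fh:
        return pd.read_csv(fh)


def dickerson_drew_shifts() -> pd.DataFrame:
    """delta-31P shifts (ppm) per step: columns ``step_id, xray_avg,
    nmr_avg, experiment``, referenced to A6pT7 (its row is exactly 0)."""
    return _load("ddd_delta31p.csv")


def dickerson_drew_couplings() -> pd.DataFrame:
    """3J(P,H3') couplings (Hz) per step: columns ``step_id, xray_avg,
    nmr_avg, experiment``."""
    return _load("ddd_j_ph3.csv")
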