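"""Packaged example data: Shasta reservoir monthly storage fractions.

The full dataset holds 42 monthly water capacities of the Shasta reservoir
(August–December readings, 1975–2016), each divided by the total capacity
of 4,552,000 acre-feet so that the values live on the unit interval.  The
censored fixture is the progressively Type-II censored subsample drawn from
it with ``m = 21`` failures and one unit removed at every failure
(``R_1 = ... = R_21 = 1``).
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .censoring import CensoringScheme, GPHCSample, classify_and_truncate

__all__ = [
    "load_dataset",
    "shasta_full",
    "shasta_censored",
    "shasta_scheme",
    "shasta_gphc_sample",
]

_FIXTURES = ("shasta_full", "shasta_censored")


def load_dataset(path_or_fixture) -> np.ndarray:
    """Load a lifetime vector from a file path or a named packaged fixture.

    Files are plain text / single-column CSV, one value per line.  Malformed
    lines are reported with their line number.
    """
    name = str(path_or_fixture)
    if name in _FIXTURES:
        source = resources.files("kwgphc.data").joinpath(f"{name}.csv")
        text = source.read_text()
    else:
        with open(name) as fh:
            text = fh.read()
    values = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip().rstrip(",")
        if not line or line.startswith("#"):
            continue
        try:
            values.append(float(line))
        except ValueError as exc:
            raise ValueError(f"{name}: malformed numeric value on line {lineno}: {line!r}") from exc
    if not values:
        raise ValueError(f"{name}: no data values found")
    return np.asarray(values, dtype=float)


def shasta_full() -> np.ndarray:
    """The 42 scaled reservoir capacities (complete sample, original order)."""
    return load_dataset("shasta_full")


def shasta_censored() -> np.ndarray:
    """The ordered 21-value progressively censored subsample."""
    return load_dataset("shasta_censored")


def shasta_scheme(case: str) -> CensoringScheme:
    """The GPHC design used for each illustration case on the Shasta data.

    All three share ``n=42, m=21, R=(1,...,1)``; Case I uses ``T=0.75,
    k=19``, Case II ``T=0.75, k=14`` and Case III ``T=0.9, k=14``.
    """
    settings = {"I": (0.75, 19), "II": (0.75, 14), "III": (0.9, 14)}
    if case not in settings:
        raise ValueError(f"case must be I, II or III, got {case!r}")
    T, k = settings[case]
    return CensoringScheme(n=42, m=21, k=k, T=T, R=(1,) * 21)


def shasta_gphc_sample(case: str) -> GPHCSample:
    """The realized GPHC sample for one of the three illustration cases.

    Case I keeps the planned removal ``R_k = 1`` at the terminal failure
    (the convention of the published analysis of this dataset) rather than
    pooling the remaining survivors into ``R_k*``; pass the times through
    :func:`kwgphc.censoring.classify_and_truncate` directly for the pooled
    variant.
    """
    scheme = shasta_scheme(case)
    terminal = "planned" if case == "I" else "pooled"
    return classify_and_truncate(shasta_censored(), scheme, case_i_terminal=terminal)
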