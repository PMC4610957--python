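"""Time-unit constants. All internal kinetics are in seconds."""

SECONDS_PER_DAY: float = 86_400.0
SECONDS_PER_WEEK: float = 7 * SECONDS_PER_DAY  # 604,800 s

#: Conversion factor between the per-cell growth-energy unit (Emad) and MeV.
MEV_PER_EMAD: float = 23234.59


def days(n: float) -> float:
    """Convert days to seconds."""
    return n * SECONDS_PER_DAY


def weeks(n: float) -> float:
    """Convert weeks to seconds (1 week = 7 days)."""
    return n * SECONDS_PER_WEEK
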