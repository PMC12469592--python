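"""Package logger; every acceptance decision is logged with its rule."""

from __future__ import annotations

import logging

logger = logging.getLogger("mrmval")


def log_decision(rule: str, threshold, value, passed: bool, context: str = "") -> None:
    """Record a pass/fail acceptance decision with the rule that produced it."""
    logger.info(
        "%s: %s (rule=%s, threshold=%s, value=%s)",
        context or rule,
        "PASS" if passed else "FAIL",
        rule,
        threshold,
        value,
    )
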