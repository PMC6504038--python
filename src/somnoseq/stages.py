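"""Sleep-stage label vocabulary and scoring-standard mapping.

Hypnograms in the Sleep-EDF corpus are scored under the older R&K standard
with tokens W, 1, 2, 3, 4, R plus M (movement time) and ? (not scored).
The five-class AASM scheme used throughout this package merges R&K stages
3 and 4 into N3 and drops M/? epochs entirely.
"""

from __future__ import annotations

from enum import IntEnum


class StageLabel(IntEnum):
    """The five AASM sleep stages, in confusion-matrix order."""

    W = 0
    N1 = 1
    N2 = 2
    N3 = 3
    REM = 4


N_STAGES = 5

#: Decoder-input token for "start of decoding"; lives in the label-embedding
#: table but never in the output classes.
SOD = N_STAGES
#: Decoder-output class for "end of decoding"; never fed back as an input
#: label when reporting per-epoch stages.
EOD = N_STAGES

STAGE_NAMES = tuple(s.name for s in StageLabel)

#: Sentinel returned by :func:`map_label` for epochs to drop.
EXCLUDED = "EXCLUDED"

_RAW_TO_STAGE = {
    "W": StageLabel.W,
    "1": StageLabel.N1,
    "2": StageLabel.N2,
    "3": StageLabel.N3,
    "4": StageLabel.N3,
    "R": StageLabel.REM,
    "M": EXCLUDED,
    "?": EXCLUDED,
}


def map_label(raw_label: str):
    """Map an R&K hypnogram token to a :class:`StageLabel` or ``EXCLUDED``.

    Stages 3 and 4 merge into N3; movement time (M) and unscored (?) epochs
    are excluded from the five-class problem.

    Parameters
    ----------
    raw_label
        One of ``W 1 2 3 4 R M ?``. Sleep-EDF long forms such as
        ``"Sleep stage W"`` are accepted and reduced to their final token.

    Raises
    ------
    ValueError
        If the token is not part of the R&K vocabulary.
    """
    token = raw_label.strip()
    if token.startswith("Sleep stage"):
        token = token[len("Sleep stage"):].strip()
    if token not in _RAW_TO_STAGE:
        raise ValueError(
            f"unrecognized hypnogram label {raw_label!r}; "
            f"expected one of {sorted(_RAW_TO_STAGE)}"
        )
    return _RAW_TO_STAGE[token]
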