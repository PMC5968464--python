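"""Survey instrument description for list-randomization (item-count) studies.

A list experiment administers *blocks* of true/false statements.  Each block
contains one sensitive statement embedded among ``J`` non-sensitive control
statements; treatment-arm respondents report only how many of the ``J + 1``
statements are true, while control-arm respondents answer every statement
directly.  :class:`ItemBlock` describes one such block together with the
design-time assumed probabilities of an affirmative answer to each item, and
:class:`SurveyDesign` describes the full instrument: the ordered blocks, the
arm-allocation ratio, the truth strata used for stratified sampling, and
which block (if any) is a tutorial.

The default instrument returned by :func:`default_design` mirrors a
five-block HIV-elicitation survey: five sensitive items (tooth brushing as a
tutorial, condom use, being HIV negative, anal sex, and refusal of a
surveillance HIV test), each with four control items.  The control-item
affirmative probabilities shipped here are plausible placeholders for design
work and simulation; a real deployment should substitute probabilities
elicited for its own population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

__all__ = [
    "ItemBlock",
    "SurveyDesign",
    "DesignError",
    "default_design",
    "STRATA",
    "truth_column",
]

#: The four truth strata of the validation design: HIV-positive linked to
#: care (status known to the individual), HIV-positive unlinked, HIV-negative,
#: and surveillance-test refusers (truth unknown to the researchers).
STRATA = ("pos_linked", "pos_unlinked", "negative", "refused")


class DesignError(ValueError):
    """Raised when an instrument description violates its invariants."""


@dataclass(frozen=True)
class ItemBlock:
    """One list-experiment block: a sensitive item plus ``J`` control items.

    Parameters
    ----------
    block_id
        Small positive integer identifying the block (1-based, unique).
    sensitive_item_id
        Identifier of the sensitive statement.
    desirability_sign
        +1 if the socially desirable answer to the sensitive statement is
        "true" (misreporting inflates the estimate), -1 if it is "false".
    control_item_ids
        Ordered identifiers of the ``J`` non-sensitive statements.
    control_probs
        Design-time assumed probabilities of an affirmative answer to each
        control item, aligned with ``control_item_ids``.
    sensitive_prob
        Design-time assumed probability of an affirmative answer to the
        sensitive item.
    """

    block_id: int
    sensitive_item_id: str
    desirability_sign: int
    control_item_ids: tuple[str, ...]
    control_probs: tuple[float, ...]
    sensitive_prob: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "control_item_ids", tuple(self.control_item_ids))
        object.__setattr__(self, "control_probs", tuple(float(p) for p in self.control_probs))
        if self.block_id < 1:
            raise DesignError(f"block_id must be >= 1, got {self.block_id}")
        if self.desirability_sign not in (+1, -1):
            raise DesignError(
                f"desirability_sign must be +1 or -1, got {self.desirability_sign}"
            )
        if len(self.control_item_ids) != len(self.control_probs):
            raise DesignError(
                f"block {self.block_id}: {len(self.control_item_ids)} control ids "
                f"but {len(self.control_probs)} probabilities"
            )
        if len(set(self.control_item_ids)) != len(self.control_item_ids):
            raise DesignError(f"block {self.block_id}: duplicate control item ids")
        for p in (*self.control_probs, self.sensitive_prob):
            if not 0.0 <= p <= 1.0:
                raise DesignError(
                    f"block {self.block_id}: probability {p} outside [0, 1]"
                )

    @property
    def n_controls(self) -> int:
        """Number of control items ``J`` in the block."""
        return len(self.control_item_ids)

    @property
    def all_probs(self) -> tuple[float, ...]:
        """Assumed probabilities of all ``J + 1`` items (controls + sensitive)."""
        return (*self.control_probs, self.sensitive_prob)


@dataclass(frozen=True)
class SurveyDesign:
    """The full list-experiment instrument.

    Holds the ordered blocks, the probability of assignment to the
    list-format arm (Arm A), the truth-stratum labels used for stratified
    randomization, and the identifier of the tutorial block (estimated like
    any other block but flagged in reports).
    """

    blocks: tuple[ItemBlock, ...]
    arm_allocation: float = 0.60
    strata: tuple[str, ...] = STRATA
    training_block_id: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        object.__setattr__(self, "strata", tuple(self.strata))
        if not self.blocks:
            raise DesignError("a design needs at least one block")
        ids = [b.block_id for b in self.blocks]
        if len(set(ids)) != len(ids):
            raise DesignError(f"duplicate block ids: {ids}")
        if not 0.0 < self.arm_allocation < 1.0:
            raise DesignError(
                f"arm_allocation must lie strictly in (0, 1), got {self.arm_allocation}"
            )
        controls = [c for b in self.blocks for c in b.control_item_ids]
        if len(set(controls)) != len(controls):
            dupes = sorted({c for c in controls if controls.count(c) > 1})
            raise DesignError(f"control items appear in more than one block: {dupes}")
        n_ctrl = {b.n_controls for b in self.blocks}
        if len(n_ctrl) != 1:
            raise DesignError(f"blocks disagree on the number of controls: {n_ctrl}")
        if self.training_block_id is not None and self.training_block_id not in ids:
            raise DesignError(
                f"training_block_id {self.training_block_id} is not a block id"
            )

    # -- convenience -------------------------------------------------------
    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_controls(self) -> int:
        """Controls per block ``J`` (identical across blocks by invariant)."""
        return self.blocks[0].n_controls

    @property
    def block_ids(self) -> tuple[int, ...]:
        return tuple(b.block_id for b in self.blocks)

    @property
    def sensitive_items(self) -> tuple[str, ...]:
        return tuple(b.sensitive_item_id for b in self.blocks)

    def block(self, block_id: int) -> ItemBlock:
        for b in self.blocks:
            if b.block_id == block_id:
                return b
        raise KeyError(f"no block with id {block_id}; have {self.block_ids}")

    def block_for_item(self, item_id: str) -> ItemBlock:
        for b in self.blocks:
            if b.sensitive_item_id == item_id:
                return b
        raise KeyError(f"no block with sensitive item {item_id!r}")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["blocks"] = [asdict(b) for b in self.blocks]
        for b in d["blocks"]:
            b["control_item_ids"] = list(b["control_item_ids"])
            b["control_probs"] = list(b["control_probs"])
        d["strata"] = list(self.strata)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SurveyDesign":
        blocks = tuple(ItemBlock(**b) for b in d["blocks"])
        return cls(
            blocks=blocks,
            arm_allocation=float(d.get("arm_allocation", 0.60)),
            strata=tuple(d.get("strata", STRATA)),
            training_block_id=d.get("training_block_id"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SurveyDesign":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def truth_column(item_id: str) -> str:
    """Canonical truth-column name for a sensitive item.

    The two items whose truth is determined by the sampling strata keep the
    historical short names (``truth_hiv_negative``, ``truth_refused``); other
    items use ``truth_<item_id>``.
    """
    if item_id == "refused_test":
        return "truth_refused"
    return f"truth_{item_id}"


#: Placeholder design-time affirmative probabilities for the 20 control
#: items.  These stand in for population-elicited values and are only used
#: for block-assignment optimisation and simulation defaults.
_DEFAULT_BLOCKS = (
    # (sensitive_item_id, sign, sensitive_prob, [(ctrl_id, prob) x 4])
    ("brushed_teeth", +1, 0.90,
     [("owns_radio", 0.55), ("ate_meat_yesterday", 0.40),
      ("visited_clinic_month", 0.30), ("walked_hour_today", 0.45)]),
    ("used_condom", +1, 0.45,
     [("owns_cellphone", 0.80), ("attended_church_week", 0.55),
      ("drank_tea_today", 0.60), ("slept_before_ten", 0.50)]),
    ("hiv_negative", +1, 0.45,
     [("has_bank_account", 0.45), ("watched_tv_yesterday", 0.50),
      ("bought_airtime_week", 0.60), ("cooked_dinner_yesterday", 0.55)]),
    ("anal_sex", -1, 0.05,
     [("travelled_town_week", 0.40), ("read_newspaper_week", 0.30),
      ("played_sport_month", 0.25), ("received_grant", 0.55)]),
    ("refused_test", -1, 0.25,
     [("grows_vegetables", 0.45), ("owns_livestock", 0.35),
      ("fetched_water_today", 0.40), ("listened_news_today", 0.60)]),
)


def default_design(arm_allocation: float = 0.60) -> SurveyDesign:
    """The five-block HIV-elicitation instrument used throughout the package.

    Five blocks of five true/false statements; one sensitive statement per
    block, position randomized.  Block 1 ("I brushed my teeth today") is the
    tutorial.  Arm A (list format) receives 60% of respondents by default.
    """
    blocks = []
    for i, (item, sign, sprob, ctrls) in enumerate(_DEFAULT_BLOCKS, start=1):
        blocks.append(
            ItemBlock(
                block_id=i,
                sensitive_item_id=item,
                desirability_sign=sign,
                control_item_ids=tuple(c for c, _ in ctrls),
                control_probs=tuple(p for _, p in ctrls),
                sensitive_prob=sprob,
            )
        )
    return SurveyDesign(
        blocks=tuple(blocks),
        arm_allocation=arm_allocation,
        strata=STRATA,
        training_block_id=1,
    )
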