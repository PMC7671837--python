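"""The Do catalog: small actionable micro-behavioural goals ("Do's").

Two kinds exist. *Core* Do's target existing habits and are selected from
intake-questionnaire answers via activation rules. *Data-driven* Do's target
one of the three behavioural variables (physical activity, social
opportunity, variety) and are dispatched when that variable's score has been
low for three consecutive days.

The default catalog reproduces the published catalog's *shape* — 89 entries,
30 of them flagged as targeting sedentary behaviour / physical activity —
with synthetic placeholder texts, because the original catalog content is
unpublished.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

CATALOG_SIZE = 89
SB_PA_TARGETED = 30

CORE, DATA_DRIVEN = "core", "data_driven"
PA, SOCIAL, VARIETY, GENERAL = "pa", "social", "variety", "general"

#: Intake questionnaire items (ordinal answers 1=never .. 5=always).
INTAKE_ITEMS: tuple[tuple[str, str], ...] = (
    ("screen_evening", "How often do you spend most evenings watching TV or in front of a screen?"),
    ("sit_work", "How often do you sit for most of your working day?"),
    ("car_short_trips", "How often do you drive for trips you could walk?"),
    ("meals_seated_screen", "How often do you eat meals in front of a screen?"),
    ("calls_seated", "How often do you take phone calls sitting down?"),
    ("same_route", "How often do you take exactly the same route on your daily trips?"),
    ("evenings_home", "How often do you spend whole evenings at home?"),
    ("lift_over_stairs", "How often do you take the lift instead of the stairs?"),
)


@dataclass
class Do:
    do_id: int
    kind: str                      # core | data_driven
    target: str                    # pa | social | variety | general
    text: str
    hyperlink: str | None = None
    sb_pa_targeted: bool = False
    #: core only: [{"item": item_id, "min_answer": 4}, ...] — any match activates
    activation_rules: list = field(default_factory=list)
    #: core only: smaller = scheduled earlier
    priority: int = 0


_CORE_SPECS = [
    # (item, min_answer, text, target, sb_pa_targeted)
    ("screen_evening", 4, "Swap the first 15 minutes of tonight's screen time for a walk around the block.", PA, True),
    ("screen_evening", 4, "Stand up and stretch at the end of every episode or program you watch.", PA, True),
    ("sit_work", 4, "Stand up every time you read or send a message at work today.", PA, True),
    ("sit_work", 4, "Hold one of today's conversations standing or walking.", PA, True),
    ("car_short_trips", 3, "Walk or cycle one trip today that you would normally drive.", PA, True),
    ("meals_seated_screen", 3, "Eat one meal today at a table with the screen off.", GENERAL, False),
    ("meals_seated_screen", 3, "After your next meal, take a 10-minute stroll before sitting back down.", GENERAL, False),
    # generic habit prompts: activated by any occurrence of the habit (>=2)
    ("calls_seated", 2, "Take your next phone call standing up or pacing.", GENERAL, False),
    ("same_route", 4, "Take a different route on one of your usual trips today.", VARIETY, False),
    ("same_route", 4, "Change the order of two of your regular stops today.", VARIETY, False),
    ("evenings_home", 4, "Spend part of this evening somewhere you haven't been this week.", SOCIAL, False),
    ("evenings_home", 4, "Invite someone to join you for a short evening walk.", SOCIAL, False),
    ("lift_over_stairs", 2, "Take the stairs every time you see a lift today.", GENERAL, False),
    ("lift_over_stairs", 2, "Get off one stop early, or park farther away, once today.", GENERAL, False),
]

_DD_PHRASES = {
    PA: (
        ["Stand up and move for two minutes", "Take a brisk 10-minute walk",
         "Do ten sit-to-stands from your chair", "March on the spot for a song",
         "Walk the long way to your next room"],
        ["every hour this morning.", "after lunch today.", "before your evening meal.",
         "while the kettle boils.", "as soon as you read this."],
    ),
    SOCIAL: (
        ["Have a coffee somewhere new", "Say hello to a neighbour",
         "Visit a shop you've never entered", "Arrange to meet a friend",
         "Sit in a different public spot"],
        ["today.", "this afternoon.", "on your next errand.",
         "before the weekend.", "somewhere within walking distance."],
    ),
    VARIETY: (
        ["Take an unfamiliar street", "Rearrange the order of your errands",
         "Do a routine task at a new time", "Explore a park you rarely visit",
         "Swap your usual seat or desk"],
        ["today.", "on your way home.", "this evening.",
         "tomorrow morning.", "at least once today."],
    ),
}

_HEART_LINK = "https://www.heartfoundation.org.au"


def default_catalog() -> list[Do]:
    """Build the 89-entry default catalog (14 core + 75 data-driven)."""
    dos: list[Do] = []
    for i, (item, min_answer, text, target, sb_pa) in enumerate(_CORE_SPECS):
        dos.append(
            Do(
                do_id=len(dos),
                kind=CORE,
                target=target,
                text=text,
                hyperlink=_HEART_LINK if i % 5 == 0 else None,
                sb_pa_targeted=sb_pa,
                activation_rules=[{"item": item, "min_answer": min_answer}],
                priority=i,
            )
        )
    for target in (PA, SOCIAL, VARIETY):
        actions, whens = _DD_PHRASES[target]
        for k in range(25):
            dos.append(
                Do(
                    do_id=len(dos),
                    kind=DATA_DRIVEN,
                    target=target,
                    text=f"{actions[k % 5]} {whens[k // 5]}",
                    hyperlink=_HEART_LINK if target == PA and k % 8 == 0 else None,
                    sb_pa_targeted=(target == PA),
                )
            )
    assert len(dos) == CATALOG_SIZE
    assert sum(d.sb_pa_targeted for d in dos) == SB_PA_TARGETED
    return dos


def write_catalog(dos: list[Do], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([asdict(d) for d in dos], fh, indent=1)


def load_catalog(path) -> list[Do]:
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    return [Do(**entry) for entry in raw]
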