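"""Synthetic phrase set for digraph counting and transcription tasks.

A small set of short, memorable English phrases written for this package in
the style of the phrase sets used to evaluate text-entry techniques.  It is
synthetic — authored here, not sampled from any published phrase corpus —
but matches their character statistics well enough to exercise digraph
counting, layout optimization and transcription simulation.
"""

from __future__ import annotations

SYNTHETIC_PHRASES: tuple[str, ...] = (
    "the quick brown fox jumps over the lazy dog",
    "my watch fell in the water",
    "prevailing winds from the east",
    "never too late to learn",
    "the early bird gets the worm",
    "all good things must end",
    "a picture is worth many words",
    "practice makes perfect every time",
    "the weather is nice today",
    "please keep this door closed",
    "we hold these truths to be evident",
    "time flies when you are having fun",
    "she sells sea shells by the shore",
    "ask not what your country can do",
    "a rolling stone gathers no moss",
    "actions speak louder than words",
    "do not count your chickens early",
    "every cloud has a silver lining",
    "an apple a day keeps trouble away",
    "honesty is always the best policy",
    "the pen is mightier than the sword",
    "when in doubt leave it out",
    "two wrongs do not make a right",
    "the squeaky wheel gets the grease",
    "people who live in glass houses",
    "you cannot judge a book by its cover",
    "absence makes the heart grow fonder",
    "a journey begins with a single step",
    "birds of a feather flock together",
    "better late than never they say",
    "fortune favors the bold and brave",
    "knowledge is power use it wisely",
    "look before you leap my friend",
    "no news is good news for now",
    "out of sight and out of mind",
    "the grass is greener over there",
    "there is no place like home",
    "where there is smoke there is fire",
    "you reap exactly what you sow",
    "still waters tend to run deep",
)


def default_corpus() -> str:
    """The synthetic phrase set as one newline-separated text blob."""
    return "\n".join(SYNTHETIC_PHRASES)


def default_prompts(n: int | None = None) -> tuple[str, ...]:
    """The first ``n`` phrases (all of them by default), for transcription."""
    return SYNTHETIC_PHRASES if n is None else SYNTHETIC_PHRASES[:n]
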