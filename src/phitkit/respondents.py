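"""Seeded synthetic respondents for headless sessions.

A respondent turns an instrument definition into an answer script
(the ``form.entity=code`` format the scripted provider reads).  Two
policies: ``uniform`` draws each choice answer uniformly from the
entity's codebook; a *fixed profile* answers every choice entity with
the same code.  The same seed always yields a byte-identical script.
"""
from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

from .instrument import EntityDef, InstrumentDef


@dataclass(frozen=True)
class SyntheticRespondent:
    seed: int
    policy: str = "uniform"          # "uniform" or "fixed"
    fixed_code: Optional[str] = None  # required when policy == "fixed"
    answer_optional: bool = False     # also answer non-required entities

    def __post_init__(self):
        if self.policy == "fixed" and self.fixed_code is None:
            raise ValueError("fixed policy needs fixed_code")
        if self.policy not in ("uniform", "fixed"):
            raise ValueError(f"unknown policy {self.policy!r}")


def _answer_for(entity: EntityDef, rng: random.Random,
                respondent: SyntheticRespondent) -> Optional[str]:
    codes = entity.codes()
    if entity.type in ("radio", "likert", "checkbox"):
        if respondent.policy == "fixed":
            return respondent.fixed_code if respondent.fixed_code in codes \
                else None
        return rng.choice(codes)
    if entity.type == "text":
        return str(rng.randint(0, 99))
    if entity.type == "date":
        year = rng.randint(1960, 2005)
        return f"{year:04d}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}"
    if entity.type == "reactionTime":
        return str(rng.randint(150, 900))       # pre-supplied latency, ms
    return None          # media entities: nothing to answer


def generate_answers(instrument: InstrumentDef,
                     respondent: SyntheticRespondent) -> str:
    """Deterministic answer script with one valid code per required
    entity (optionally all entities)."""
    if instrument.kind != "interactive":
        raise ValueError("script instruments take no answers")
    rng = random.Random(respondent.seed)
    lines = []
    for form in instrument.forms:
        for entity in form.entities:
            if not entity.required and not respondent.answer_optional:
                continue
            answer = _answer_for(entity, rng, respondent)
            if answer is not None:
                lines.append(f"{form.name}.{entity.name}={answer}")
    return "\n".join(lines) + ("\n" if lines else "")
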