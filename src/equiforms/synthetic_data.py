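"""Study-shaped synthetic data: item bank, randomised design, GRM responses.

The generator emulates a crossed paper/electronic administration study at a
community mental-health clinic: each participant completes both half-forms
of a depression item bank, one on paper and one electronically (on a mobile
phone or tablet), with an 8-cell randomisation of device, modality order
and form order.  Defaults reproduce the study conditions: 129 participants
with latent depression severity theta ~ Normal(0.91, 0.98^2) on the
community-normed reporting scale, truncated to [-4, 4], and no true
modality, form or interaction effects (the null of equivalence).

Non-null scenarios inject additive location shifts of theta for specific
modalities, for Form B, or for modality-by-form cells — the simplest
alternative consistent with an equivalence framing.  Per-item differential
functioning is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .bank_splitter import FormSplit
from .grm_engine import ItemBank, ItemParameters, ResponsePattern, _star_probs, _bank_arrays

__all__ = [
    "DEVICES",
    "MODALITIES",
    "SimConfig",
    "CellAssignment",
    "AdministrationRecord",
    "make_synthetic_bank",
    "randomize_cells",
    "simulate_cohort",
    "cohort_to_frame",
    "design_frame",
    "write_bank_csv",
    "read_bank_csv",
    "read_pairing_csv",
    "write_pairing_csv",
]

DEVICES = ("mobile_phone", "tablet")
MODALITIES = ("paper", "electronic")
FORMS = ("A", "B")


class SimConfig(BaseModel):
    """Cohort-simulation settings.

    Effects are additive shifts of the effective theta at which responses
    are generated.  ``modality_effect`` keys may be ``paper``,
    ``electronic`` (both devices), or a specific device name;
    ``interaction_effect`` keys are ``"<modality>:<form>"`` (for example
    ``"electronic:B"``).  All effects default to zero — the equivalence
    null.
    """

    n_participants: int = Field(default=129, ge=2)
    theta_mean: float = 0.91
    theta_sd: float = Field(default=0.98, gt=0)
    modality_effect: dict[str, float] = Field(default_factory=dict)
    form_effect: float = 0.0
    interaction_effect: dict[str, float] = Field(default_factory=dict)
    seed: int

    @model_validator(mode="after")
    def _check_effect_keys(self):
        valid_mod = set(MODALITIES) | set(DEVICES)
        for k in self.modality_effect:
            if k not in valid_mod:
                raise ValueError(f"unknown modality key {k!r}")
        for k in self.interaction_effect:
            parts = k.split(":")
            if len(parts) != 2 or parts[0] not in valid_mod or parts[1] not in FORMS:
                raise ValueError(f"interaction key must be '<modality>:<form>', got {k!r}")
        return self


@dataclass(frozen=True)
class CellAssignment:
    """One participant's draw from the 2 x 2 x 2 randomisation."""

    device: str  # mobile_phone | tablet
    modality_order: str  # paper_first | electronic_first
    form_order: str  # A_first | B_first


@dataclass(frozen=True)
class AdministrationRecord:
    """One participant x modality x form administration with its responses."""

    participant_id: str
    device: str
    modality: str  # paper | electronic
    modality_order: str
    form: str  # A | B
    form_order: str
    responses: ResponsePattern
    true_theta: float

    @property
    def analysis_modality(self) -> str:
        """Three-level modality used in the analyses: paper or the device."""
        return "paper" if self.modality == "paper" else self.device


# ---------------------------------------------------------------------------
# Synthetic item bank
# ---------------------------------------------------------------------------

def make_synthetic_bank(n_items: int = 28, n_pairs: int = 14, seed: int = 0) -> ItemBank:
    """Generate a content-paired GRM bank shaped like a clinical depression bank.

    Discriminations are drawn uniformly on [1.5, 4.0] (strongly
    discriminating, as published depression banks are) and the four ordered
    thresholds lie within [-1.5, 3.5], the usual span for clinical-severity
    items whose categories mostly separate above the community mean.  The
    two members of a pair share a common prototype with small jitter, so
    paired items are psychometrically similar — as clinically-matched items
    would be.  Deterministic for a given seed.
    """
    if n_items != 2 * n_pairs or n_pairs < 1:
        raise ValueError(f"need n_items == 2 * n_pairs >= 2, got {n_items}, {n_pairs}")
    rng = np.random.default_rng(seed)
    items: list[ItemParameters] = []
    pair_of: dict[str, str] = {}
    pair_ids: dict[str, tuple[str, str]] = {}
    width = len(str(n_items))
    for p in range(n_pairs):
        proto_a = rng.uniform(1.5, 4.0)
        b1 = rng.uniform(-1.2, 0.3)
        gaps = rng.uniform(0.35, 1.05, size=3)
        proto_b = b1 + np.concatenate([[0.0], np.cumsum(gaps)])
        member_ids = []
        for m in range(2):
            a = float(np.clip(proto_a * np.exp(rng.normal(0.0, 0.05)), 1.5, 4.0))
            b = proto_b + rng.normal(0.0, 0.08, size=4)
            b = np.clip(np.sort(b), -1.5, 3.5)
            # keep thresholds strictly increasing after clipping
            for k in range(1, 4):
                if b[k] <= b[k - 1]:
                    b[k] = b[k - 1] + 1e-3
            iid = f"item{2 * p + m + 1:0{width}d}"
            items.append(
                ItemParameters(
                    iid, a, tuple(b), label=f"synthetic depressive symptom item {2 * p + m + 1}"
                )
            )
            member_ids.append(iid)
        i, j = member_ids
        pair_of[i], pair_of[j] = j, i
        pair_ids[f"P{p + 1:02d}"] = (i, j)
    return ItemBank(items, pair_of=pair_of, pair_ids=pair_ids)


# ---------------------------------------------------------------------------
# Design randomisation
# ---------------------------------------------------------------------------

def randomize_cells(participant_ids: Sequence[str], seed: int) -> list[CellAssignment]:
    """Independently randomise each participant into the 8-cell design.

    Three independent fair coin flips per participant: electronic device
    (mobile phone vs tablet), modality order (paper first vs electronic
    first), and form order (A first vs B first).
    """
    rng = np.random.default_rng(seed)
    flips = rng.integers(2, size=(len(participant_ids), 3))
    return [
        CellAssignment(
            device=DEVICES[f[0]],
            modality_order=("paper_first", "electronic_first")[f[1]],
            form_order=("A_first", "B_first")[f[2]],
        )
        for f in flips
    ]


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _effect_shift(config: SimConfig, modality: str, device: str, form: str) -> float:
    """Resolve the additive theta shift for one administration."""
    eff = 0.0
    me = config.modality_effect
    if modality == "paper":
        eff += me.get("paper", 0.0)
        mod_keys = ("paper",)
    else:
        eff += me.get(device, me.get("electronic", 0.0))
        mod_keys = (device, "electronic")
    if form == "B":
        eff += config.form_effect
    ie = config.interaction_effect
    for mk in mod_keys:
        key = f"{mk}:{form}"
        if key in ie:
            eff += ie[key]
            break
    return eff


def _draw_responses(rng: np.random.Generator, theta: float, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw: X = #{k : u < P*_k(theta)} has the GRM distribution."""
    star = _star_probs(np.atleast_1d(theta), a, b)[0, :, 1:-1]  # (I, 4)
    u = rng.uniform(size=star.shape[0])
    return (u[:, None] < star).sum(axis=1)


def simulate_cohort(
    config: SimConfig, bank: ItemBank, split: FormSplit
) -> list[AdministrationRecord]:
    """Simulate the crossed design: two administrations per participant.

    Each participant's latent theta is drawn from the truncated normal
    prior; the first administration uses the first modality and first form
    of their randomised orders, the second the complements — so every
    participant sees both forms, one per modality, and the electronic one
    on their assigned device.  Responses are drawn from the GRM at the
    effect-shifted theta.
    """
    split.validate_against(bank)
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    ids = [f"p{i + 1:03d}" for i in range(n)]
    cells = randomize_cells(ids, seed=int(rng.integers(2**31)))

    # truncated-normal draw by rejection (negligible mass lost at ±4)
    thetas = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(config.theta_mean, config.theta_sd, size=n - filled)
        keep = draw[(draw >= -4.0) & (draw <= 4.0)]
        thetas[filled : filled + keep.size] = keep
        filled += keep.size

    form_items = {
        "A": (split.form_a, *_bank_arrays(bank.subset(split.form_a))),
        "B": (split.form_b, *_bank_arrays(bank.subset(split.form_b))),
    }
    records: list[AdministrationRecord] = []
    for pid, cell, theta in zip(ids, cells, thetas):
        first_mod = "paper" if cell.modality_order == "paper_first" else "electronic"
        first_form = "A" if cell.form_order == "A_first" else "B"
        sequence = [
            (first_mod, first_form),
            ("electronic" if first_mod == "paper" else "paper", "B" if first_form == "A" else "A"),
        ]
        for modality, form in sequence:
            item_ids, a, b = form_items[form]
            eff_theta = theta + _effect_shift(config, modality, cell.device, form)
            resp = _draw_responses(rng, eff_theta, a, b)
            records.append(
                AdministrationRecord(
                    participant_id=pid,
                    device=cell.device,
                    modality=modality,
                    modality_order=cell.modality_order,
                    form=form,
                    form_order=cell.form_order,
                    responses=ResponsePattern(tuple(item_ids), tuple(int(r) for r in resp)),
                    true_theta=float(theta),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Tabular views and file formats
# ---------------------------------------------------------------------------

def cohort_to_frame(records: Sequence[AdministrationRecord]) -> pd.DataFrame:
    """Long-format response table: one row per participant x item response."""
    rows = []
    for rec in records:
        for iid, resp in zip(rec.responses.item_ids, rec.responses.responses):
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "modality": rec.analysis_modality,
                    "form": rec.form,
                    "item_id": iid,
                    "response": resp,
                }
            )
    return pd.DataFrame(rows)


def design_frame(records: Sequence[AdministrationRecord]) -> pd.DataFrame:
    """One row per participant with their 8-cell design assignment."""
    seen: dict[str, dict] = {}
    for rec in records:
        seen.setdefault(
            rec.participant_id,
            {
                "participant_id": rec.participant_id,
                "device": rec.device,
                "modality_order": rec.modality_order,
                "form_order": rec.form_order,
            },
        )
    return pd.DataFrame(list(seen.values()))


def write_bank_csv(bank: ItemBank, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"item_id": it.item_id, "label": it.label, "a": it.a,
             "b1": it.b[0], "b2": it.b[1], "b3": it.b[2], "b4": it.b[3]}
            for it in bank
        ]
    )
    df.to_csv(path, index=False)


def read_bank_csv(path: str | Path, pairing: dict[str, tuple[str, str]] | None = None) -> ItemBank:
    """Read an item-parameter CSV (`item_id,label,a,b1,b2,b3,b4`)."""
    df = pd.read_csv(path, dtype={"item_id": str})
    items = [
        ItemParameters(
            str(r.item_id),
            float(r.a),
            (float(r.b1), float(r.b2), float(r.b3), float(r.b4)),
            label="" if pd.isna(r.label) else str(r.label),
        )
        for r in df.itertuples()
    ]
    if pairing is None:
        return ItemBank(items)
    pair_of: dict[str, str] = {}
    for i, j in pairing.values():
        pair_of[i], pair_of[j] = j, i
    return ItemBank(items, pair_of=pair_of, pair_ids=pairing)


def read_pairing_csv(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a pairing CSV (`pair_id,item_id_1,item_id_2`)."""
    df = pd.read_csv(path, dtype=str)
    return {r.pair_id: (r.item_id_1, r.item_id_2) for r in df.itertuples()}


def write_pairing_csv(bank: ItemBank, path: str | Path) -> None:
    rows = [
        {"pair_id": pid, "item_id_1": i, "item_id_2": j} for pid, (i, j) in bank.pairs()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
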