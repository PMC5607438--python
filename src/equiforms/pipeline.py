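"""End-to-end runner: generate -> split -> simulate -> score -> analyze -> report.

A single master seed drives every stochastic stage through per-stage
derived seeds (``seed_for(master, tag)``, a hash of the master seed and a
stage name), so any stage can be rerun independently and a rerun of the
whole pipeline with the same config reproduces every numeric output
exactly.  Floating-point numbers in written artifacts carry 6 significant
digits; all internal computation is at full precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import bank_splitter, equivalence_analysis as ea, synthetic_data as sd
from .bank_splitter import FormSplit
from .grm_engine import FormScorer, ItemBank, MISSING

__all__ = [
    "seed_for",
    "CohortSpec",
    "SyntheticBankSpec",
    "AnalysisSpec",
    "RunConfig",
    "score_cohort",
    "score_response_table",
    "build_report",
    "run_pipeline",
    "make_fixtures",
]

log = logging.getLogger("equiforms")


def seed_for(master_seed: int, stage: str) -> int:
    """Derive a stage seed (< 2^31) deterministically from the master seed."""
    digest = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

class SyntheticBankSpec(BaseModel):
    n_items: int = 28
    n_pairs: int = 14


class CohortSpec(BaseModel):
    """Simulation settings without a seed (the pipeline derives one)."""

    n_participants: int = Field(default=129, ge=2)
    theta_mean: float = 0.91
    theta_sd: float = Field(default=0.98, gt=0)
    modality_effect: dict[str, float] = Field(default_factory=dict)
    form_effect: float = 0.0
    interaction_effect: dict[str, float] = Field(default_factory=dict)

    def to_sim_config(self, seed: int) -> sd.SimConfig:
        return sd.SimConfig(seed=seed, **self.model_dump())


class AnalysisSpec(BaseModel):
    alpha: float = Field(default=0.05, gt=0, lt=1)
    df_method: str = "containment"
    flag_rule: str = "boundary"  # currently the only built-in rule


class RunConfig(BaseModel):
    """Full pipeline configuration.

    The item bank comes from exactly one source: a parameter file (with a
    pairing file) or the synthetic generator.  The seed is mandatory and
    feeds every stochastic stage via derived per-stage seeds.
    """

    seed: int
    bank_file: str | None = None
    pairing_file: str | None = None
    synthetic_bank: SyntheticBankSpec | None = None
    sim: CohortSpec = Field(default_factory=CohortSpec)
    analysis: AnalysisSpec = Field(default_factory=AnalysisSpec)
    out_dir: str = "equiforms_run"

    @model_validator(mode="after")
    def _one_bank_source(self):
        if (self.bank_file is None) == (self.synthetic_bank is None):
            raise ValueError("configure exactly one bank source: bank_file or synthetic_bank")
        if self.bank_file is not None and self.pairing_file is None:
            raise ValueError("a bank_file requires a pairing_file")
        return self


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_cohort(
    records: Sequence[sd.AdministrationRecord],
    bank: ItemBank,
    split: FormSplit,
    flag_rule: Callable[[pd.DataFrame], pd.Series] | None = None,
) -> pd.DataFrame:
    """Score every administration by ML and assemble the analysis table.

    Returns one row per administration with columns
    ``participant_id, modality, form, theta, se, boundary, n_items_used,
    true_theta, flagged``; ``modality`` is the three-level analysis factor
    (paper / mobile_phone / tablet).
    """
    scorers = {
        "A": FormScorer(bank.subset(split.form_a)),
        "B": FormScorer(bank.subset(split.form_b)),
    }
    by_form: dict[str, list[int]] = {"A": [], "B": []}
    for idx, rec in enumerate(records):
        by_form[rec.form].append(idx)

    rows: list[dict] = [None] * len(records)  # type: ignore[list-item]
    for form, indices in by_form.items():
        if not indices:
            continue
        scorer = scorers[form]
        matrix = np.array(
            [
                [MISSING if r is None else r for r in records[i].responses.responses]
                for i in indices
            ],
            dtype=int,
        )
        for i, est in zip(indices, scorer.score_many(matrix)):
            rec = records[i]
            rows[i] = {
                "participant_id": rec.participant_id,
                "modality": rec.analysis_modality,
                "form": rec.form,
                "theta": est.theta,
                "se": est.se,
                "boundary": est.boundary,
                "n_items_used": est.n_items_used,
                "true_theta": rec.true_theta,
            }
    df = pd.DataFrame(rows)
    rule = flag_rule if flag_rule is not None else ea.boundary_flag_rule
    return ea.flag_participants(df, rule)


def score_response_table(responses: pd.DataFrame, bank: ItemBank) -> pd.DataFrame:
    """Score a long-format response table (one row per item response).

    Administrations are the unique ``(participant_id, modality, form)``
    groups; blank responses count as missing.
    """
    scorers: dict[tuple[str, ...], FormScorer] = {}
    rows = []
    for (pid, modality, form), grp in responses.groupby(
        ["participant_id", "modality", "form"], sort=False
    ):
        item_ids = tuple(grp["item_id"])
        if item_ids not in scorers:
            scorers[item_ids] = FormScorer(bank.subset(item_ids))
        resp = [None if pd.isna(r) else int(r) for r in grp["response"]]
        est = scorers[item_ids].score(resp)
        rows.append(
            {
                "participant_id": pid,
                "modality": modality,
                "form": form,
                "theta": est.theta,
                "se": est.se,
                "boundary": est.boundary,
                "n_items_used": est.n_items_used,
            }
        )
    return ea.flag_participants(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _round_sig(x, digits: int = 6):
    if isinstance(x, float):
        return float(f"{x:.{digits}g}") if np.isfinite(x) else None
    if isinstance(x, dict):
        return {k: _round_sig(v, digits) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round_sig(v, digits) for v in x]
    return x


def build_report(scored: pd.DataFrame, analysis: AnalysisSpec | None = None) -> dict:
    """Run the full analysis suite on a scored dataset and collect results.

    Mirrors the study's reporting: descriptive summary; interaction and
    main-effects mixed models on the full data and on the unflagged
    subset; three repeated-measures t tests and the phone-vs-tablet
    independent-groups t test.
    """
    analysis = analysis or AnalysisSpec()
    ea.validate_scored(scored)

    def model_dict(m: ea.MixedModelResult) -> dict:
        return {
            "terms": {k: dataclasses.asdict(v) for k, v in m.terms.items()},
            "fixed_effects": m.fixed_effects,
            "random_intercept_var": m.random_intercept_var,
            "residual_var": m.residual_var,
            "n_obs": m.n_obs,
            "n_subjects": m.n_subjects,
            "converged": m.converged,
        }

    inter_full, main_full = ea.fit_equivalence_models(
        scored, use_flagged=True, df_method=analysis.df_method
    )
    report: dict = {
        "summary": ea.summarize_scores(scored).to_dict(orient="records"),
        "mixed_models": {
            "full_data": {"interaction": model_dict(inter_full), "main_effects": model_dict(main_full)},
        },
        "n_participants": int(scored["participant_id"].nunique()),
        "n_flagged": int(scored.loc[scored["flagged"], "participant_id"].nunique()),
        "alpha": analysis.alpha,
    }
    unflagged = scored[~scored["flagged"].astype(bool)]
    if unflagged["participant_id"].nunique() >= 3 and unflagged["participant_id"].nunique() < report["n_participants"]:
        try:
            inter_un, main_un = ea.fit_equivalence_models(
                scored, use_flagged=False, df_method=analysis.df_method
            )
            report["mixed_models"]["unflagged"] = {
                "interaction": model_dict(inter_un),
                "main_effects": model_dict(main_un),
            }
        except ValueError as exc:  # e.g. a device group emptied by exclusion
            report["mixed_models"]["unflagged"] = {"error": str(exc)}
    t_tests: dict = {}
    for comp in ea.PAIRED_COMPARISONS:
        try:
            t_tests[comp] = dataclasses.asdict(ea.paired_t(scored, comp))
        except ValueError as exc:
            t_tests[comp] = {"error": str(exc)}
    phone = scored.loc[scored["modality"] == "mobile_phone", "theta"]
    tablet = scored.loc[scored["modality"] == "tablet", "theta"]
    if len(phone) >= 2 and len(tablet) >= 2:
        t_tests["phone_vs_tablet"] = dataclasses.asdict(
            ea.independent_t(phone, tablet, "Mobile phone", "Tablet")
        )
    report["t_tests"] = t_tests
    return report


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _load_bank(config: RunConfig) -> ItemBank:
    if config.bank_file is not None:
        pairing = sd.read_pairing_csv(config.pairing_file)
        return sd.read_bank_csv(config.bank_file, pairing=pairing)
    spec = config.synthetic_bank
    return sd.make_synthetic_bank(spec.n_items, spec.n_pairs, seed=seed_for(config.seed, "bank"))


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full study pipeline and write all artifacts to ``out_dir``.

    Writes: the bank and pairing CSVs (when synthetic), ``split.json``,
    ``information_curves.csv``, ``responses.csv``, ``design.csv``,
    ``scored.csv``, ``report.json`` and ``run.log``.  Returns the report.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        from . import __version__

        log.info("equiforms %s; master seed %d", __version__, config.seed)
        bank = _load_bank(config)
        if config.bank_file is None:
            sd.write_bank_csv(bank, out / "bank.csv")
            sd.write_pairing_csv(bank, out / "pairing.csv")
        log.info("bank: %d items, %d pairs", len(bank), len(bank.pairs()))

        split0 = bank_splitter.initial_split(bank, seed=seed_for(config.seed, "split"))
        split = bank_splitter.balance_by_swaps(split0, bank)
        log.info(
            "split: initial gap %.6g, balanced gap %.6g after %d swap(s)",
            split0.info_gap, split.info_gap, len(split.swaps_applied),
        )
        bank_splitter.write_split_json(split, out / "split.json")
        curves = bank_splitter.information_curves(split, bank)
        curves.to_csv(out / "information_curves.csv", index=False, float_format="%.6g")

        sim_cfg = config.sim.to_sim_config(seed=seed_for(config.seed, "cohort"))
        records = sd.simulate_cohort(sim_cfg, bank, split)
        sd.cohort_to_frame(records).to_csv(out / "responses.csv", index=False)
        sd.design_frame(records).to_csv(out / "design.csv", index=False)
        log.info("cohort: %d participants, %d administrations", sim_cfg.n_participants, len(records))

        scored = score_cohort(records, bank, split)
        scored.to_csv(out / "scored.csv", index=False, float_format="%.6g")
        log.info("scored: %d boundary estimates, %d flagged participants",
                 int(scored["boundary"].sum()),
                 int(scored.loc[scored["flagged"], "participant_id"].nunique()))

        report = build_report(scored, config.analysis)
        report["config"] = json.loads(config.model_dump_json())
        (out / "report.json").write_text(json.dumps(_round_sig(report), indent=2) + "\n")
        log.info("report written to %s", out / "report.json")
        return report
    finally:
        log.removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def make_fixtures(seed: int, out_dir: str | Path | None = None) -> dict:
    """Produce the small deterministic fixture set used by the test suite.

    A 4-pair (8-item) bank, a 12-participant cohort on its balanced split,
    and dense-grid-search theta values (step 1e-3) for every administration
    — an optimiser-independent scoring oracle.  Returns the fixtures; also
    writes them when ``out_dir`` is given.
    """
    bank = sd.make_synthetic_bank(8, 4, seed=seed_for(seed, "fixture-bank"))
    split = bank_splitter.balance_by_swaps(
        bank_splitter.initial_split(bank, seed=seed_for(seed, "fixture-split")), bank
    )
    cfg = sd.SimConfig(n_participants=12, seed=seed_for(seed, "fixture-cohort"))
    records = sd.simulate_cohort(cfg, bank, split)

    from .grm_engine import _bank_arrays, _cat_probs

    grid = np.linspace(-4.0, 4.0, 8001)  # 1e-3 steps
    dense_logp = {}
    for form, ids in (("A", split.form_a), ("B", split.form_b)):
        a, b = _bank_arrays(bank.subset(ids))
        with np.errstate(divide="ignore"):
            dense_logp[form] = np.log(_cat_probs(grid, a, b))  # (T, I, 5)
    oracle = []
    for rec in records:
        resp = rec.responses.as_array()
        ll = dense_logp[rec.form][:, np.arange(resp.size), resp].sum(axis=1)
        oracle.append(
            {
                "participant_id": rec.participant_id,
                "modality": rec.analysis_modality,
                "form": rec.form,
                "grid_theta": float(grid[int(np.argmax(ll))]),
            }
        )
    fixtures = {
        "bank": bank,
        "split": split,
        "records": records,
        "oracle": oracle,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sd.write_bank_csv(bank, out / "fixture_bank.csv")
        sd.write_pairing_csv(bank, out / "fixture_pairing.csv")
        bank_splitter.write_split_json(split, out / "fixture_split.json")
        sd.cohort_to_frame(records).to_csv(out / "fixture_responses.csv", index=False)
        sd.design_frame(records).to_csv(out / "fixture_design.csv", index=False)
        (out / "fixture_oracle.json").write_text(json.dumps(oracle, indent=2) + "\n")
    return fixtures
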