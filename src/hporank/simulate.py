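"""Simulated patient cohorts from disease penetrance tables.

A disease model lists the phenotype terms of a single-gene Mendelian
disorder together with each term's penetrance f_p (the probability that
an affected patient exhibits it) and an optional sex restriction.  Four
corruption scenarios emulate clinical reality:

optimal
    Each disease phenotype is admitted independently with probability
    f_p (sex is drawn first, uniformly, and sex-restricted phenotypes
    conflicting with it are never admitted).  Patients are resampled
    until they carry at least one term.
noise
    floor(n_optimal / 2) extra terms drawn uniformly from the universe
    terms that do not annotate the causative gene directly or indirectly.
imprecision
    Every optimal term is replaced by a uniformly chosen proper ancestor
    other than the root (terms whose only proper ancestor is the root are
    kept unchanged); replacements that collide are collapsed as a set.
imprecision_noise
    The imprecision terms plus the same noise terms drawn for the
    noise-only patient.

All scenarios for one base patient share the same optimal draw and the
same noise draw, so scenario contrasts are paired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Sequence

import numpy as np

from hporank.annotations import AnnotationIndex
from hporank.ontology import Ontology

logger = logging.getLogger(__name__)

SCENARIOS = ("optimal", "noise", "imprecision", "imprecision_noise")
MAX_RESAMPLE_ATTEMPTS = 1000


@dataclass(frozen=True)
class DiseasePhenotype:
    term: str
    penetrance: float
    gender_restriction: str = "none"  # none | male | female

    def __post_init__(self) -> None:
        if not (0.0 < self.penetrance <= 1.0):
            raise ValueError(
                f"penetrance must be in (0, 1], got {self.penetrance} for {self.term}"
            )
        if self.gender_restriction not in ("none", "male", "female"):
            raise ValueError(
                f"gender_restriction must be none/male/female, got "
                f"{self.gender_restriction!r}"
            )


@dataclass(frozen=True)
class DiseaseModel:
    """A single-causative-gene disease with per-phenotype penetrance."""

    omim_id: str
    causative_gene: str
    phenotypes: tuple[DiseasePhenotype, ...]

    def validate(self, index: AnnotationIndex) -> None:
        """Check every phenotype term directly annotates the causative gene.

        The baseline disease set is defined as the intersection of the
        disease's terms and the causative gene's direct annotations, so a
        violation indicates a malformed disease table.
        """
        direct = index.direct.get(self.causative_gene, frozenset())
        for ph in self.phenotypes:
            tid = index.ontology.resolve(ph.term)
            if tid not in direct:
                raise ValueError(
                    f"disease {self.omim_id}: term {ph.term} does not directly "
                    f"annotate causative gene {self.causative_gene}"
                )


@dataclass(frozen=True)
class SimulatedPatient:
    patient_id: str
    disease: str
    causative_gene: str
    sex: str  # male | female
    optimal_terms: frozenset[str]
    noise_terms: frozenset[str] = frozenset()
    scenario: str = "optimal"
    terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not self.terms:
            object.__setattr__(self, "terms", self.optimal_terms)


def _admissible(ph: DiseasePhenotype, sex: str) -> bool:
    return ph.gender_restriction in ("none", sex)


def sample_optimal(
    model: DiseaseModel,
    ontology: Ontology,
    index: AnnotationIndex,
    seed: int | np.random.Generator,
    patient_id: str = "",
) -> SimulatedPatient:
    """Draw one optimal patient for a disease.

    Sex first (uniform draw; male if the draw exceeds 0.5), then each
    phenotype independently with probability f_p, skipping phenotypes
    whose sex restriction conflicts.  The whole patient is resampled
    (bounded attempts) until at least one term is present, preserving
    the relative penetrance structure of multi-term draws.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(MAX_RESAMPLE_ATTEMPTS):
        sex = "male" if rng.random() > 0.5 else "female"
        terms = {
            ontology.resolve(ph.term)
            for ph in model.phenotypes
            if _admissible(ph, sex) and rng.random() <= ph.penetrance
        }
        if terms:
            return SimulatedPatient(
                patient_id=patient_id or model.omim_id,
                disease=model.omim_id,
                causative_gene=model.causative_gene,
                sex=sex,
                optimal_terms=frozenset(terms),
                scenario="optimal",
            )
    raise RuntimeError(
        f"disease {model.omim_id}: no non-empty phenotype draw in "
        f"{MAX_RESAMPLE_ATTEMPTS} attempts (effective penetrance ~ 0)"
    )


def noise_universe(index: AnnotationIndex, causative_gene: str) -> list[str]:
    """Universe terms that do not annotate the gene directly or indirectly.

    A term annotates a gene indirectly when any of its descendants does,
    i.e. when the gene appears in the term's propagated set; equivalently
    the excluded terms are the gene's direct annotations plus all their
    ancestors.
    """
    return [
        t
        for t in index.universe
        if causative_gene not in index.propagated.get(t, frozenset())
    ]


def noise_count(n_optimal: int) -> int:
    """Number of noise terms: half the optimal count, floored."""
    return n_optimal // 2


def add_noise(
    patient: SimulatedPatient,
    index: AnnotationIndex,
    seed: int | np.random.Generator,
    allowed: Sequence[str] | None = None,
) -> SimulatedPatient:
    """Attach floor(n_optimal/2) noise terms unrelated to the causative gene.

    Terms are drawn uniformly without replacement from the disease's
    allowed noise set (computed from the index unless passed in); each
    patient gets an independent draw.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = noise_count(len(patient.optimal_terms))
    pool = list(allowed) if allowed is not None else noise_universe(
        index, patient.causative_gene
    )
    if n > len(pool):
        raise ValueError(
            f"requested {n} noise terms but only {len(pool)} terms do not "
            f"annotate gene {patient.causative_gene}"
        )
    chosen = rng.choice(len(pool), size=n, replace=False) if n else []
    noise = frozenset(pool[i] for i in chosen)
    return replace(
        patient,
        noise_terms=noise,
        scenario="noise",
        terms=patient.optimal_terms | noise,
    )


def add_imprecision(
    patient: SimulatedPatient,
    ontology: Ontology,
    seed: int | np.random.Generator,
) -> SimulatedPatient:
    """Replace each optimal term with a random non-root proper ancestor.

    Terms whose only proper ancestor is the root have no admissible
    replacement and are kept unchanged.  Replacements are independent
    per term; colliding replacements collapse because term sets are sets.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: set[str] = set()
    for term in sorted(patient.optimal_terms):
        eligible = sorted(ontology.ancestors(term) - {ontology.root})
        if eligible:
            out.add(eligible[rng.integers(0, len(eligible))])
        else:
            out.add(term)
    return replace(patient, scenario="imprecision", terms=frozenset(out))


def build_cohort(
    models: Sequence[DiseaseModel],
    ontology: Ontology,
    index: AnnotationIndex,
    n_per_disease: int,
    scenarios: Sequence[str] = SCENARIOS,
    seed: int = 0,
) -> list[SimulatedPatient]:
    """Generate a full cohort: n base patients per disease x scenarios.

    Each base patient is expanded into one row per requested scenario;
    the noise and imprecision+noise rows share the noise terms drawn once
    for that base patient, and the imprecision rows share the optimal
    draw.  Total size = len(models) * n_per_disease * len(scenarios).
    Fully reproducible from the seed.
    """
    if n_per_disease < 1:
        raise ValueError("n_per_disease must be >= 1")
    unknown = set(scenarios) - set(SCENARIOS)
    if unknown:
        raise ValueError(f"unknown scenarios: {sorted(unknown)}")
    cohort: list[SimulatedPatient] = []
    need_noise = "noise" in scenarios or "imprecision_noise" in scenarios
    for di, model in enumerate(sorted(models, key=lambda m: m.omim_id)):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(di,))
        )
        allowed = noise_universe(index, model.causative_gene) if need_noise else None
        for i in range(n_per_disease):
            pid = f"{model.omim_id}-{i:04d}"
            base = sample_optimal(model, ontology, index, rng, patient_id=pid)
            noisy = add_noise(base, index, rng, allowed=allowed) if need_noise else None
            imprecise = (
                add_imprecision(base, ontology, rng)
                if "imprecision" in scenarios or "imprecision_noise" in scenarios
                else None
            )
            for scen in scenarios:
                if scen == "optimal":
                    cohort.append(base)
                elif scen == "noise":
                    cohort.append(noisy)
                elif scen == "imprecision":
                    cohort.append(imprecise)
                elif scen == "imprecision_noise":
                    cohort.append(
                        replace(
                            imprecise,
                            noise_terms=noisy.noise_terms,
                            scenario="imprecision_noise",
                            terms=imprecise.terms | noisy.noise_terms,
                        )
                    )
    return cohort


# -- tabular I/O -----------------------------------------------------------


def load_disease_table(path_or_file: str | IO[str]) -> list[DiseaseModel]:
    """Read a tab-delimited disease table.

    Columns: omim_id, causative_gene, term, penetrance,
    gender_restriction (optional, default ``none``); one phenotype per
    row, ``#`` comment lines skipped.
    """
    if isinstance(path_or_file, str):
        with open(path_or_file) as fh:
            return load_disease_table(fh)
    rows: dict[tuple[str, str], list[DiseasePhenotype]] = {}
    for line in path_or_file:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise ValueError(f"malformed disease table row: {line!r}")
        omim, gene, term, pen = fields[:4]
        gender = fields[4] if len(fields) > 4 and fields[4] else "none"
        rows.setdefault((omim, gene), []).append(
            DiseasePhenotype(term=term, penetrance=float(pen), gender_restriction=gender)
        )
    return [
        DiseaseModel(omim_id=omim, causative_gene=gene, phenotypes=tuple(phens))
        for (omim, gene), phens in sorted(rows.items())
    ]


def write_disease_table(models: Iterable[DiseaseModel], path_or_file: str | IO[str]) -> None:
    if isinstance(path_or_file, str):
        with open(path_or_file, "w") as fh:
            write_disease_table(models, fh)
        return
    fh = path_or_file
    fh.write("#omim_id\tcausative_gene\tterm\tpenetrance\tgender_restriction\n")
    for m in models:
        for ph in m.phenotypes:
            fh.write(
                f"{m.omim_id}\t{m.causative_gene}\t{ph.term}\t"
                f"{ph.penetrance:.4f}\t{ph.gender_restriction}\n"
            )


def write_cohort(cohort: Iterable[SimulatedPatient], path_or_file: str | IO[str]) -> None:
    """Write a cohort as tab-delimited rows with comma-joined term lists."""
    if isinstance(path_or_file, str):
        with open(path_or_file, "w") as fh:
            write_cohort(cohort, fh)
        return
    fh = path_or_file
    fh.write(
        "#patient_id\tdisease\tcausative_gene\tscenario\tsex\tterms\t"
        "optimal_terms\tnoise_terms\n"
    )
    for p in cohort:
        fh.write(
            f"{p.patient_id}\t{p.disease}\t{p.causative_gene}\t{p.scenario}\t"
            f"{p.sex}\t{','.join(sorted(p.terms))}\t"
            f"{','.join(sorted(p.optimal_terms))}\t"
            f"{','.join(sorted(p.noise_terms))}\n"
        )


def load_cohort(path_or_file: str | IO[str]) -> list[SimulatedPatient]:
    if isinstance(path_or_file, str):
        with open(path_or_file) as fh:
            return load_cohort(fh)
    out: list[SimulatedPatient] = []
    for line in path_or_file:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        pid, disease, gene, scen, sex, terms, opt, noise = line.split("\t")
        out.append(
            SimulatedPatient(
                patient_id=pid,
                disease=disease,
                causative_gene=gene,
                sex=sex,
                optimal_terms=frozenset(t for t in opt.split(",") if t),
                noise_terms=frozenset(t for t in noise.split(",") if t),
                scenario=scen,
                terms=frozenset(t for t in terms.split(",") if t),
            )
        )
    return out
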