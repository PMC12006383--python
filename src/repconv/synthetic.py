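"""Synthetic multi-patient IGH repertoire generator with known ground truth.

Emulates the structure of annotated case/control repertoires so every
downstream stage (clone assignment, convergent clustering, sharing
statistics, disease-list derivation, enrichment scoring, SHM and usage
features) can be exercised without access to patient data:

* per-subject private clones with random CDR-H3 junctions;
* "public" clones planted across multiple case subjects (and optionally
  controls), each carrier copy perturbed by a configurable number of
  amino-acid mismatches so that recovery requires the 85%-identity
  clustering rule rather than exact string matching;
* isotype labels with isotype-dependent somatic-hypermutation rates
  applied to a fixed toy germline V segment;
* power-law (zipf) clone-size UMI counts.

All randomness flows from a single root seed through per-subject
spawned streams, so outputs are bit-identical across runs and adding a
subject does not perturb the other subjects' draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .airr_io import ISOTYPES, Rearrangement, RepertoireSample

#: Fixed toy germline V segment (300 nt).  SHM quantification only needs
#: an aligned observed/germline pair; gene identity is carried by the
#: ``v_call`` label independently, so a single synthetic segment suffices.
TOY_GERMLINE_V = (
    "ATCATGTAAAGATAACTGTCACGTTTTACGGATGAGGAAATTGTTTCAACACAATGGAAT"
    "AACCCCAGCCCAGGGCAAGGCAGCACTCCGTAAGCGACGGAGCAGTCCACCCATTTATTG"
    "GCACGCGGTCTCCCTTCCGATGACACCAACGGCTCCGCCCATCGGGTTTATTGGGTTTTG"
    "TGGAAGCTGTCGATCACCAGCCTAGGCAAGGGTAAGGGTGCTAAATGCAGGACTGCGAGG"
    "AACAAACGTTCTCTGCGACTAGGAGGTTGACCGTGGCGAGATCCCGTGAAGATAAACCTA"
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

#: One representative codon per amino acid, used to back-translate
#: junction_aa into a junction_nt consistent with it.
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "AGT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

#: Identity threshold the convergent-clustering stage uses; planted
#: variants must stay co-clusterable under it.
_CLUSTER_IDENTITY = 0.85


def _normalized(d: Mapping, cast=float) -> dict:
    total = float(sum(d.values()))
    return {k: cast(v) / total for k, v in d.items()}


def _default_cdr3_lengths() -> dict[int, float]:
    """Roughly Gaussian junction-length law centred near 15 aa (IMGT
    junction, anchors included), spanning 9-23."""
    lengths = np.arange(9, 24)
    w = np.exp(-0.5 * ((lengths - 15.0) / 3.0) ** 2)
    return _normalized(dict(zip((int(x) for x in lengths), w)))


def _default_v_freqs() -> dict[str, float]:
    return {
        "IGHV3-23": 0.12, "IGHV4-39": 0.08, "IGHV3-30": 0.08, "IGHV4-34": 0.07,
        "IGHV4-59": 0.07, "IGHV1-69": 0.07, "IGHV3-7": 0.06, "IGHV3-21": 0.06,
        "IGHV5-51": 0.06, "IGHV1-2": 0.06, "IGHV1-18": 0.05, "IGHV3-48": 0.05,
        "IGHV4-4": 0.05, "IGHV3-15": 0.05, "IGHV2-5": 0.04, "IGHV6-1": 0.03,
    }


def _default_j_freqs() -> dict[str, float]:
    # IGHJ4 dominates human IGH repertoires, with IGHJ6 and IGHJ5 next.
    return {
        "IGHJ1": 0.01, "IGHJ2": 0.02, "IGHJ3": 0.06,
        "IGHJ4": 0.50, "IGHJ5": 0.16, "IGHJ6": 0.25,
    }


def _default_shm_rates() -> dict[str, float]:
    # Per-base substitution probabilities over the V region: naive-like
    # IgM/IgD low, class-switched isotypes progressively higher.
    return {
        "IGHM": 0.005, "IGHD": 0.005,
        "IGHG3": 0.015, "IGHG1": 0.02, "IGHG2": 0.025, "IGHG4": 0.025,
        "IGHA1": 0.03, "IGHA2": 0.03, "IGHE": 0.02,
    }


def _default_isotype_freqs() -> dict[str, float]:
    return {
        "IGHM": 0.35, "IGHD": 0.05, "IGHG1": 0.20, "IGHG2": 0.10,
        "IGHG3": 0.05, "IGHG4": 0.02, "IGHA1": 0.15, "IGHA2": 0.07,
        "IGHE": 0.01,
    }


class SimulationError(ValueError):
    """Raised for infeasible or inconsistent simulation configurations."""


@dataclass
class SimulationConfig:
    """Parameters of one simulated case/control cohort.

    Probability maps must sum to 1 (tolerance 1e-9).  ``public_penetrance``
    is the probability that each case subject independently carries a
    given planted public clone; when ``public_in_controls`` is set,
    controls carry it with ``control_penetrance`` (defaults to the case
    value).  ``public_variant_mismatches`` amino-acid substitutions are
    applied to every planted copy so that cross-subject recovery relies
    on the identity-threshold clustering; planted junction lengths are
    restricted to lengths where any two perturbed copies remain within
    the 85% identity radius of each other (co-clusterable whichever
    copy becomes the cluster representative).
    """

    n_case_subjects: int = 16
    n_control_subjects: int = 8
    clones_per_subject: int = 500
    public_clone_count: int = 50
    public_penetrance: float = 0.6
    public_in_controls: bool = False
    control_penetrance: float | None = None
    public_variant_mismatches: int = 1
    public_shm_multiplier: float = 1.0
    clone_size_alpha: float = 2.5
    shm_rate_by_isotype: dict[str, float] = field(default_factory=_default_shm_rates)
    isotype_frequencies: dict[str, float] = field(default_factory=_default_isotype_freqs)
    cdr3_length_distribution: dict[int, float] = field(default_factory=_default_cdr3_lengths)
    v_gene_frequencies: dict[str, float] = field(default_factory=_default_v_freqs)
    j_gene_frequencies: dict[str, float] = field(default_factory=_default_j_freqs)
    case_group: str = "case"
    control_group: str = "control"
    tissue: str = "LN"
    seed: int = 0
    #: Seed of the public-prototype stream; defaults to ``seed``.  Two
    #: cohorts simulated with the same ``public_seed`` (and clone count
    #: and distributions) share identical planted prototypes while
    #: their subjects stay independent — the discovery/validation setup.
    public_seed: int | None = None

    def validate(self) -> None:
        if self.n_case_subjects < 1 or self.n_control_subjects < 0:
            raise SimulationError("subject counts must be positive")
        if self.clones_per_subject < 1:
            raise SimulationError("clones_per_subject must be positive")
        if not (0.0 < self.public_penetrance <= 1.0):
            raise SimulationError("public_penetrance must lie in (0, 1]")
        if self.public_clone_count > 0 and self.n_case_subjects < 2:
            raise SimulationError(
                "public_clone_count > 0 requires n_case_subjects >= 2 "
                "(a public clone needs at least two potential carriers)"
            )
        if self.clone_size_alpha <= 1.0:
            raise SimulationError("clone_size_alpha must exceed 1 for a proper power law")
        for name, dist in (
            ("shm_rate_by_isotype", None),
            ("isotype_frequencies", self.isotype_frequencies),
            ("cdr3_length_distribution", self.cdr3_length_distribution),
            ("v_gene_frequencies", self.v_gene_frequencies),
            ("j_gene_frequencies", self.j_gene_frequencies),
        ):
            if dist is None:
                continue
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise SimulationError(f"{name} probabilities must sum to 1")
        unknown = set(self.isotype_frequencies) - set(ISOTYPES)
        if unknown:
            raise SimulationError(f"unrecognised isotypes: {sorted(unknown)}")
        missing = set(self.isotype_frequencies) - set(self.shm_rate_by_isotype)
        if missing:
            raise SimulationError(f"shm_rate_by_isotype lacks rates for {sorted(missing)}")
        for iso, rate in self.shm_rate_by_isotype.items():
            if not (0.0 <= rate <= 0.3):
                raise SimulationError(f"shm rate for {iso} outside [0, 0.3]")
        if self.public_clone_count > 0 and not self._plantable_lengths():
            raise SimulationError(
                "no junction length satisfies "
                "2*public_variant_mismatches/length <= 0.15; planted copies "
                "could not remain co-clusterable"
            )

    def _plantable_lengths(self) -> dict[int, float]:
        """Junction lengths whose planted variants stay co-clusterable.

        Any carrier copy may end up as the cluster representative, and
        two copies each perturbed by ``public_variant_mismatches``
        substitutions can differ at up to twice that many positions, so
        the binding condition is 2*mismatches/length <= 1 - 0.85 (not
        merely mismatches/length: identity to the unperturbed prototype
        is not what the greedy clustering measures).
        """
        ok = {
            length: p
            for length, p in self.cdr3_length_distribution.items()
            if 2 * self.public_variant_mismatches / length <= 1.0 - _CLUSTER_IDENTITY + 1e-12
        }
        return _normalized(ok) if ok else {}


@dataclass
class GroundTruth:
    """Planted truth for one simulated dataset.

    ``planted_public`` maps each planted clone id to its carrier subject
    set; ``true_clone_id`` and ``true_mutation_count`` are keyed by
    sequence_id.  ``public_prototypes`` records, per planted clone, the
    (v_gene, j_gene, junction_aa) of the unperturbed prototype.
    """

    planted_public: dict[str, set[str]] = field(default_factory=dict)
    public_prototypes: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    true_clone_id: dict[str, str] = field(default_factory=dict)
    true_mutation_count: dict[str, int] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "planted_public": {k: sorted(v) for k, v in self.planted_public.items()},
            "public_prototypes": {k: list(v) for k, v in self.public_prototypes.items()},
            "true_clone_id": self.true_clone_id,
            "true_mutation_count": self.true_mutation_count,
        }


def mutate_vregion(
    germline: str, rate: float, rng: np.random.Generator
) -> tuple[str, int]:
    """Apply independent per-base substitutions to a germline segment.

    Each base is replaced (by a uniformly chosen *different* base) with
    probability ``rate``; returns the mutated string and the exact count
    of substituted positions.
    """
    if not (0.0 <= rate <= 1.0):
        raise SimulationError("mutation rate must lie in [0, 1]")
    n = len(germline)
    hit = rng.random(n) < rate
    count = int(hit.sum())
    if count == 0:
        return germline, 0
    seq = np.frombuffer(germline.encode(), dtype="S1").copy()
    idx = np.flatnonzero(hit)
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    # draw a uniformly different base: offset 1..3 in the 4-letter ring
    base_idx = np.searchsorted(alphabet, seq[idx])
    offsets = rng.integers(1, 4, size=count)
    seq[idx] = alphabet[(base_idx + offsets) % 4]
    return seq.tobytes().decode(), count


def _draw_categorical(rng: np.random.Generator, dist: Mapping, size: int) -> list:
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=size, p=probs)
    return [keys[i] for i in idx]


def _random_junction(rng: np.random.Generator, length: int) -> str:
    """Random IMGT junction with conserved C...W anchors."""
    interior = "".join(
        AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=length - 2)
    )
    return "C" + interior + "W"


def _perturb_junction(rng: np.random.Generator, junction: str, n_mismatches: int) -> str:
    """Substitute ``n_mismatches`` interior positions to different residues."""
    if n_mismatches == 0:
        return junction
    interior = list(junction[1:-1])
    pos = rng.choice(len(interior), size=min(n_mismatches, len(interior)), replace=False)
    for p in pos:
        choices = AMINO_ACIDS.replace(interior[p], "")
        interior[p] = choices[rng.integers(0, len(choices))]
    return junction[0] + "".join(interior) + junction[-1]


def _back_translate(junction_aa: str) -> str:
    return "".join(_CODON[a] for a in junction_aa)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[RepertoireSample], GroundTruth]:
    """Generate one case/control cohort with planted public clones.

    Each subject yields one sample of exactly ``clones_per_subject``
    clones (one rearrangement per clone); planted public clones replace
    private slots so per-subject clone counts stay constant.
    Deterministic given ``config.seed``.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    n_subjects = config.n_case_subjects + config.n_control_subjects
    _, *subject_ss = root.spawn(1 + n_subjects)
    public_seed = config.seed if config.public_seed is None else config.public_seed
    public_rng = np.random.default_rng(np.random.SeedSequence((public_seed, 0x9E3779B9)))

    truth = GroundTruth()
    case_ids = [f"case{(i + 1):02d}" for i in range(config.n_case_subjects)]
    control_ids = [f"ctrl{(i + 1):02d}" for i in range(config.n_control_subjects)]

    # --- public clone prototypes and carrier masks (own stream) ---
    prototypes: list[tuple[str, str, str, str]] = []  # (clone_id, v, j, junction_aa)
    carriers: dict[str, set[str]] = {}
    if config.public_clone_count > 0:
        lengths = _draw_categorical(
            public_rng, config._plantable_lengths(), config.public_clone_count
        )
        vs = _draw_categorical(public_rng, config.v_gene_frequencies, config.public_clone_count)
        js = _draw_categorical(public_rng, config.j_gene_frequencies, config.public_clone_count)
        ctrl_pen = (
            config.control_penetrance
            if config.control_penetrance is not None
            else config.public_penetrance
        )
        # prototypes first (their draws depend only on public_seed and the
        # clone count, never on cohort size), carrier masks second
        for i in range(config.public_clone_count):
            cid = f"pub{i:03d}"
            junction = _random_junction(public_rng, int(lengths[i]))
            prototypes.append((cid, vs[i], js[i], junction))
            truth.public_prototypes[cid] = (vs[i], js[i], junction)
        for cid, _, _, _ in prototypes:
            carry = {
                s
                for s in case_ids
                if public_rng.random() < config.public_penetrance
            }
            if config.public_in_controls:
                carry |= {s for s in control_ids if public_rng.random() < ctrl_pen}
            carriers[cid] = carry
            truth.planted_public[cid] = set(carry)

    # --- per-subject repertoires (independent streams) ---
    samples: list[RepertoireSample] = []
    for subject, ss in zip(case_ids + control_ids, subject_ss):
        rng = np.random.default_rng(ss)
        is_case = subject in set(case_ids)
        carried = [p for p in prototypes if subject in carriers.get(p[0], ())]
        n_private = config.clones_per_subject - len(carried)
        if n_private < 0:
            raise SimulationError(
                f"subject {subject} carries {len(carried)} public clones, "
                f"exceeding clones_per_subject={config.clones_per_subject}"
            )

        clone_specs: list[tuple[str, str, str, str, bool]] = []
        for cid, v, j, junction in carried:
            variant = _perturb_junction(rng, junction, config.public_variant_mismatches)
            clone_specs.append((cid, v, j, variant, True))
        lengths = _draw_categorical(rng, config.cdr3_length_distribution, n_private)
        vs = _draw_categorical(rng, config.v_gene_frequencies, n_private)
        js = _draw_categorical(rng, config.j_gene_frequencies, n_private)
        for k in range(n_private):
            clone_specs.append(
                (
                    f"{subject}_priv{k:04d}",
                    vs[k],
                    js[k],
                    _random_junction(rng, int(lengths[k])),
                    False,
                )
            )

        isotypes = _draw_categorical(rng, config.isotype_frequencies, len(clone_specs))
        umis = rng.zipf(config.clone_size_alpha, size=len(clone_specs))
        rearrangements = []
        for k, ((cid, v, j, junction_aa, is_public), iso) in enumerate(
            zip(clone_specs, isotypes)
        ):
            rate = config.shm_rate_by_isotype[iso]
            if is_public:
                rate = min(0.3, rate * config.public_shm_multiplier)
            mutated, n_mut = mutate_vregion(TOY_GERMLINE_V, rate, rng)
            seq_id = f"{subject}_seq{k:05d}"
            rearrangements.append(
                Rearrangement(
                    sequence_id=seq_id,
                    v_call=f"{v}*01",
                    j_call=f"{j}*01",
                    junction_aa=junction_aa,
                    junction_nt=_back_translate(junction_aa),
                    isotype=iso,
                    umi_count=int(umis[k]),
                    v_sequence_alignment=mutated,
                    v_germline_alignment=TOY_GERMLINE_V,
                )
            )
            truth.true_clone_id[seq_id] = cid
            truth.true_mutation_count[seq_id] = n_mut

        samples.append(
            RepertoireSample(
                sample_id=f"{subject}_{config.tissue}",
                subject_id=subject,
                tissue=config.tissue,
                group=config.case_group if is_case else config.control_group,
                rearrangements=rearrangements,
            )
        )
    return samples, truth
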