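"""Seeded generators for every input the pipeline consumes.

The generators stand in for the curated moonlighting-protein benchmark:
they emit FASTA sequences, PSI-BLAST-style ASCII profiles, an
AAindex1-format property table, eight-state secondary-structure strings, a
GO ontology with annotation counts, and labels — all deterministic under a
seed, with per-view class signal dialed by ``SynthConfig.signal``.

Signal model
------------
Seq    class-1 sequences embed short motifs at a rate proportional to the
       Seq signal (Poisson number of insertions per sequence).
PSSM   class-1 profiles receive an additive log-odds bias on a fixed column
       subset, proportional to the PSSM signal.
AA     class-1 residue background is exponentially tilted toward a fixed
       composition direction, proportional to the AA signal.
SS     class-1 state distribution is tilted toward helix/strand states,
       proportional to the SS signal.

At signal 0 every generator draws the two classes from one distribution.
Per-record randomness is derived by hashing the record id together with the
global seed, so regenerating a subset is stable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import MelmpError
from .goneg import GoDag, ProteinAnnotation
from .seqfeat import AA_ALPHABET, SS_ALPHABET, ProfileMatrix, ProteinRecord

#: PSI-BLAST's native profile column order (differs from the alphabetical
#: order used in-memory; the reader remaps).
PSIBLAST_ORDER = tuple("ARNDCQEGHILKMFPSTWYV")


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic benchmark.

    ``n_per_class`` defaults to 200+200, close to the 268 positive / 162
    negative scale of the curated benchmark while keeping runtimes
    desk-scale. ``signal`` maps each view to a class-separation strength in
    [0, 1]; 0 makes that view's distribution label-independent.
    """

    n_per_class: tuple[int, int] = (200, 200)
    length_range: tuple[int, int] = (100, 300)
    signal: dict = field(
        default_factory=lambda: {"Seq": 1.0, "PSSM": 1.0, "AA": 1.0, "SS": 1.0}
    )
    motifs: tuple[str, ...] = ("WYWKC", "HMHDL", "CCKWM")
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_class) < 1:
            raise MelmpError("need at least one record per class")
        if any(len(m) > self.length_range[0] for m in self.motifs):
            raise MelmpError("motif longer than the minimum sequence length")


def _record_rng(cfg: SynthConfig, record_id: str, salt: int = 0) -> np.random.Generator:
    """Per-record stream: global seed + CRC32 of the id, stable under subsetting."""
    return np.random.default_rng(
        [cfg.seed, zlib.crc32(record_id.encode()) & 0x7FFFFFFF, salt]
    )


# ---------------------------------------------------------------------------
# sequences


def _aa_background(cfg: SynthConfig, label: int) -> np.ndarray:
    probs = np.full(20, 1.0 / 20)
    if label == 1 and cfg.signal.get("AA", 0.0) > 0:
        tilt = np.zeros(20)
        for i, aa in enumerate(AA_ALPHABET):
            tilt[i] = 0.6 if aa in "DEKR" else -0.2
        probs = probs * np.exp(cfg.signal["AA"] * tilt)
        probs /= probs.sum()
    return probs


def gen_sequences(cfg: SynthConfig) -> tuple[list[ProteinRecord], np.ndarray]:
    """Generate labelled protein records (labels: class 0 then class 1)."""
    records: list[ProteinRecord] = []
    labels: list[int] = []
    for label, n in enumerate(cfg.n_per_class):
        for i in range(n):
            rid = f"SYN{label}_{i:04d}"
            rng = _record_rng(cfg, rid)
            length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
            probs = _aa_background(cfg, label)
            seq = list(rng.choice(list(AA_ALPHABET), size=length, p=probs))
            if label == 1 and cfg.signal.get("Seq", 0.0) > 0:
                n_ins = rng.poisson(6.0 * cfg.signal["Seq"])
                for _ in range(n_ins):
                    motif = cfg.motifs[int(rng.integers(len(cfg.motifs)))]
                    start = int(rng.integers(0, length - len(motif) + 1))
                    seq[start : start + len(motif)] = list(motif)
            records.append(ProteinRecord(id=rid, residues="".join(seq)))
            labels.append(label)
    return records, np.asarray(labels, dtype=int)


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# profiles

#: Profile columns biased in class 1 (alphabetical indices of C, H, W).
_BIASED_COLUMNS = tuple(AA_ALPHABET.index(a) for a in "CHW")


def make_profile(record: ProteinRecord, label: int, cfg: SynthConfig) -> ProfileMatrix:
    """Synthetic L x 20 log-odds profile; class bias on a fixed column subset."""
    rng = _record_rng(cfg, record.id, salt=1)
    L = len(record.residues)
    scores = rng.integers(-4, 5, size=(L, 20)).astype(float)
    for j, res in enumerate(record.residues):
        if res in AA_ALPHABET:
            scores[j, AA_ALPHABET.index(res)] += 5.0
    if label == 1 and cfg.signal.get("PSSM", 0.0) > 0:
        scores[:, list(_BIASED_COLUMNS)] += round(3.0 * cfg.signal["PSSM"])
    return ProfileMatrix(scores=scores, sequence=record.residues)


def write_ascii_pssm(profile: ProfileMatrix, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII layout (native column order)."""
    order = [AA_ALPHABET.index(a) for a in PSIBLAST_ORDER]
    with open(path, "w") as fh:
        fh.write(
            "\nLast position-specific scoring matrix computed, weighted "
            "observed percentages rounded down, information per position, "
            "and relative weight of gapless real matches to pseudocounts\n"
        )
        letters = "  ".join(PSIBLAST_ORDER)
        fh.write(f"            {letters}   {letters}\n")
        for j, res in enumerate(profile.sequence, start=1):
            row = profile.scores[j - 1, order]
            cells = " ".join(f"{int(v):3d}" for v in row)
            pct = " ".join(f"{0:3d}" for _ in row)
            fh.write(f"{j:5d} {res} {cells}  {pct}  0.00 0.00\n")
        fh.write("\n                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1337     0.3113\n")


def gen_profiles(
    records: list[ProteinRecord],
    labels: np.ndarray,
    cfg: SynthConfig,
    outdir: str | Path,
) -> list[Path]:
    """Write one ASCII profile per record; returns the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec, label in zip(records, labels):
        path = outdir / f"{rec.id}.pssm"
        write_ascii_pssm(make_profile(rec, int(label), cfg), path)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# property table


def gen_property_table(
    P: int = 566, n_missing: int = 13, cfg: SynthConfig = SynthConfig()
) -> str:
    """AAindex1-format text with ``P`` properties, ``n_missing`` of them
    containing an "NA" value (exercising the missing-value filter)."""
    if P < 1:
        raise MelmpError("need at least one property")
    if n_missing > P:
        raise MelmpError("cannot have more missing properties than properties")
    rng = np.random.default_rng([cfg.seed, 0xAA])
    missing = set(rng.choice(P, size=n_missing, replace=False).tolist())
    # AAindex1 value rows: A R N D C Q E G H I then L K M F P S T W Y V
    row1, row2 = tuple("ARNDCQEGHI"), tuple("LKMFPSTWYV")
    chunks = []
    for p in range(P):
        vals = {a: rng.normal() for a in AA_ALPHABET}
        na_at = None
        if p in missing:
            na_at = AA_ALPHABET[int(rng.integers(20))]
        lines = [f"H SYNP{p:04d}", "D synthetic physicochemical scale", "I " + " ".join(
            f"{a}/{b}" for a, b in zip(row1, row2)
        )]
        for row in (row1, row2):
            cells = [
                "     NA" if a == na_at else f"{vals[a]:7.3f}" for a in row
            ]
            lines.append("  " + " ".join(cells))
        lines.append("//")
        chunks.append("\n".join(lines))
    return "\n".join(chunks) + "\n"


# ---------------------------------------------------------------------------
# secondary structure

#: Baseline eight-state composition (coil/helix/strand dominated).
_SS_BASE = {
    "C": 0.26, "H": 0.30, "E": 0.20, "T": 0.11,
    "S": 0.07, "G": 0.03, "B": 0.02, "I": 0.01,
}
#: Tilt direction applied to class 1 (toward helix/strand, away from coil).
_SS_TILT = {"H": 0.8, "E": 0.5, "C": -0.8, "T": -0.3}


def gen_ss(
    records: list[ProteinRecord], labels: np.ndarray, cfg: SynthConfig
) -> dict[str, str]:
    """Per-record eight-state strings, length-matched to the sequences.

    States are drawn in geometric runs (mean length 4) from a per-class
    state distribution; the class-1 distribution is tilted by the SS
    signal.
    """
    states = list(_SS_BASE)
    base = np.array([_SS_BASE[s] for s in states])
    out: dict[str, str] = {}
    for rec, label in zip(records, labels):
        rng = _record_rng(cfg, rec.id, salt=2)
        probs = base.copy()
        if label == 1 and cfg.signal.get("SS", 0.0) > 0:
            tilt = np.array([_SS_TILT.get(s, 0.0) for s in states])
            probs = probs * np.exp(cfg.signal["SS"] * tilt)
            probs /= probs.sum()
        chars: list[str] = []
        while len(chars) < len(rec.residues):
            state = rng.choice(states, p=probs)
            run = 1 + int(rng.geometric(0.25))
            chars.extend([state] * run)
        out[rec.id] = "".join(chars[: len(rec.residues)])
    return out


def write_ss(ss: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, s in ss.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GO ontology with planted accept/reject proteins


def gen_go_dag(
    cfg: SynthConfig = SynthConfig(),
) -> tuple[GoDag, list[ProteinAnnotation], dict[str, str]]:
    """A three-namespace ontology with planted negative-set fixtures.

    Annotation counts are chosen so that leaves of a "band" group share a
    simRel of ~0.18 (inside the (0.1, 0.5) selection band via an ancestor
    with p=0.4) and leaves of the "tight" group share ~0.62 (outside the
    band via an ancestor with p=0.02). Planted proteins either satisfy all
    three selection principles or violate exactly one; the returned map
    gives each planted protein's expected outcome
    ("accept" or "reject:<principle>").
    """
    dag = GoDag()

    def add(term: str, ns: str, anno: int, parents: set[str]) -> None:
        dag.namespace[term] = ns
        dag.parents[term] = set(parents)
        dag.anno[term] = anno

    def add_group(prefix: str, ns: str, root: str, group_anno: int,
                  leaf_anno: int, n_leaves: int = 8) -> list[str]:
        g = f"{prefix}G"
        add(g, ns, group_anno, {root})
        leaves = []
        for i in range(n_leaves):
            leaf = f"{prefix}L{i}"
            add(leaf, ns, leaf_anno, {g})
            leaves.append(leaf)
        return leaves

    # BP: root freq 1000; two band groups (p=0.4, leaves p=0.05) and one
    # tight group (p=0.02, leaves p=0.002)
    add("GO:B0000", "BP", 180, set())
    b1 = add_group("GO:B1", "BP", "GO:B0000", 0, 50)
    b2 = add_group("GO:B2", "BP", "GO:B0000", 0, 50)
    b3 = add_group("GO:B3", "BP", "GO:B0000", 4, 2)

    # MF: root freq 1000; two band groups
    add("GO:M0000", "MF", 200, set())
    m1 = add_group("GO:M1", "MF", "GO:M0000", 0, 50)
    m2 = add_group("GO:M2", "MF", "GO:M0000", 0, 50)

    # CC: root plus flat leaves
    add("GO:C0000", "CC", 500, set())
    cc = []
    for i in range(4):
        term = f"GO:C1L{i}"
        add(term, "CC", 125, {"GO:C0000"})
        cc.append(term)

    annotations = [
        ProteinAnnotation("NEG001", frozenset(b1)),
        ProteinAnnotation("NEG002", frozenset(b2 + m1[:2] + cc[:1])),
        ProteinAnnotation("POS001", frozenset(b1[:7])),
        ProteinAnnotation("POS002", frozenset(b1[:4] + b2[:4])),
        ProteinAnnotation("POS003", frozenset(b3)),
        ProteinAnnotation("POS004", frozenset(b1 + m1[:2] + m2[:2])),
    ]
    expected = {
        "NEG001": "accept",
        "NEG002": "accept",
        "POS001": "reject:too-few-terms",
        "POS002": "reject:bp-clusters",
        "POS003": "reject:bp-clusters",
        "POS004": "reject:mf-clusters",
    }
    dag.validate()
    return dag, annotations, expected


def write_obo(dag: GoDag, path: str | Path) -> None:
    """Write the ontology as a minimal OBO file (id / name / namespace / is_a)."""
    ns_long = {"BP": "biological_process", "MF": "molecular_function",
               "CC": "cellular_component"}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for term in sorted(dag.namespace):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: synthetic term {term}\n")
            fh.write(f"namespace: {ns_long.get(dag.namespace[term], dag.namespace[term])}\n")
            for parent in sorted(dag.parents.get(term, ())):
                fh.write(f"is_a: {parent} ! synthetic term {parent}\n")


def write_edgelist(dag: GoDag, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(dag.namespace):
            parents = sorted(dag.parents.get(term, ()))
            if not parents:
                fh.write(f"{term}\t\t{dag.namespace[term]}\n")
            for parent in parents:
                fh.write(f"{term}\t{parent}\t{dag.namespace[term]}\n")


def write_term_counts(dag: GoDag, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sorted(dag.namespace):
            fh.write(f"{term}\t{dag.anno.get(term, 0)}\n")


def write_annotations(annotations: list[ProteinAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            for term in sorted(ann.terms):
                fh.write(f"{ann.protein_id}\t{term}\n")


def write_labels(
    records: list[ProteinRecord], labels: np.ndarray, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for rec, label in zip(records, labels):
            fh.write(f"{rec.id}\t{int(label)}\n")


def simulate_to_dir(cfg: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit the full synthetic input bundle under ``outdir``.

    Returns the path of each artifact: FASTA, labels, profile directory,
    AAindex file, SS file, and the GO bundle (OBO, edge list, annotation
    counts, protein annotations).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, labels = gen_sequences(cfg)
    paths = {
        "fasta": outdir / "sequences.fasta",
        "labels": outdir / "labels.tsv",
        "pssm_dir": outdir / "pssm",
        "aaindex": outdir / "aaindex1.txt",
        "ss": outdir / "ss.fasta",
        "obo": outdir / "go" / "ontology.obo",
        "edgelist": outdir / "go" / "edges.tsv",
        "term_counts": outdir / "go" / "term_counts.tsv",
        "annotations": outdir / "go" / "annotations.tsv",
    }
    write_fasta(records, paths["fasta"])
    write_labels(records, labels, paths["labels"])
    gen_profiles(records, labels, cfg, paths["pssm_dir"])
    paths["aaindex"].write_text(gen_property_table(cfg=cfg))
    write_ss(gen_ss(records, labels, cfg), paths["ss"])
    (outdir / "go").mkdir(exist_ok=True)
    dag, annotations, _ = gen_go_dag(cfg)
    write_obo(dag, paths["obo"])
    write_edgelist(dag, paths["edgelist"])
    write_term_counts(dag, paths["term_counts"])
    write_annotations(annotations, paths["annotations"])
    return paths
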