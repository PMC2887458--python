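"""Secondary structure and backbone hydrogen-bond annotation.

Annotations stratify fitted force constants and parameterize the
modified GNM. Two sources are supported: a classic fixed-width DSSP
output file, or an internal assignment that reproduces the
Kabsch–Sander electrostatic hydrogen-bond criterion from backbone
coordinates (amide hydrogens are reconstructed from peptide geometry).

Secondary-structure classes are deliberately coarse: "H" (α-helix),
"E" (strand; DSSP codes E and B merged) and "other".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import ConformerEnsemble
from .exceptions import AnnotationError, FormatError

#: Kabsch–Sander H-bond energy threshold, kcal/mol.
HBOND_ENERGY_CUTOFF = -0.5

#: Kabsch–Sander electrostatics prefactor: q1·q2·332 kcal·Å/mol.
_KS_FACTOR = 0.084 * 332.0

#: Amide N-H bond length used for hydrogen reconstruction, Å.
_NH_BOND = 1.01


@dataclass
class ResidueAnnotation:
    """Per-residue secondary structure code and H-bond partners."""

    ss_code: str = "other"
    hbond_partners: set[int] = field(default_factory=set)
    source: str = "internal"


def contact_order(i: int, j: int) -> int:
    """Sequential separation |i − j| between two residues of one chain.

    k = 1 corresponds to bonded (backbone pseudo-bond) pairs; helical
    hydrogen-bond partners on consecutive turns have k = 4.
    """
    if i == j:
        raise ValueError("contact order undefined for a residue with itself")
    return abs(i - j)


def _map_ss(code: str) -> str:
    if code == "H":
        return "H"
    if code in ("E", "B"):
        return "E"
    return "other"


def read_dssp(path: str, n_residues: int | None = None
              ) -> list[ResidueAnnotation]:
    """Parse a classic fixed-width DSSP output file.

    Extracts the one-letter structure code (column 17) and backbone
    hydrogen bonds from the four N-H→O / O→H-N fields; a partner is
    recorded when its energy is below −0.5 kcal/mol. Partner offsets in
    DSSP are relative to the sequential residue counter.
    """
    entries: list[tuple[int, str, list[tuple[int, float]]]] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("  #  RESIDUE"):
                in_table = True
                continue
            if not in_table or len(line) < 50:
                continue
            if line[13] == "!":  # chain break
                entries.append((-1, "other", []))
                continue
            try:
                seq = int(line[0:5])
            except ValueError:
                raise FormatError(f"bad DSSP residue line: {line!r}")
            ss = _map_ss(line[16])
            bonds = []
            for start in (39, 50, 61, 72):
                fld = line[start:start + 11]
                if "," not in fld:
                    continue
                off_s, en_s = fld.split(",", 1)
                try:
                    off, en = int(off_s), float(en_s)
                except ValueError:
                    raise FormatError(f"bad DSSP H-bond field {fld!r}")
                if off != 0 and en < HBOND_ENERGY_CUTOFF:
                    bonds.append((off, en))
            entries.append((seq, ss, bonds))
    if not entries:
        raise FormatError(f"{path}: no DSSP residue table found")
    if n_residues is not None and len(entries) != n_residues:
        raise AnnotationError(
            f"DSSP has {len(entries)} residues but ensemble has "
            f"{n_residues}")
    anns = [ResidueAnnotation(ss_code=ss, source="dssp-file")
            for _, ss, _ in entries]
    for idx, (_, _, bonds) in enumerate(entries):
        for off, _ in bonds:
            j = idx + off
            if 0 <= j < len(anns):
                anns[idx].hbond_partners.add(j)
                anns[j].hbond_partners.add(idx)
    return anns


def _reconstruct_amide_h(N: np.ndarray, C: np.ndarray,
                         O: np.ndarray) -> np.ndarray:
    """Amide H positions: 1.01 Å from N, trans to the preceding carbonyl O.

    Residue 0 has no preceding peptide plane; its position is NaN and it
    is skipped as a donor.
    """
    n = N.shape[0]
    H = np.full((n, 3), np.nan)
    for i in range(1, n):
        v = C[i - 1] - O[i - 1]
        H[i] = N[i] + _NH_BOND * v / np.linalg.norm(v)
    return H


def _ks_energy(N_d, H_d, C_a, O_a) -> float:
    """Kabsch–Sander electrostatic energy of one donor/acceptor pair."""
    r_on = np.linalg.norm(O_a - N_d)
    r_ch = np.linalg.norm(C_a - H_d)
    r_oh = np.linalg.norm(O_a - H_d)
    r_cn = np.linalg.norm(C_a - N_d)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9  # atom clash: treat as maximal bond, as DSSP does
    return _KS_FACTOR * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)


def assign_hbonds_internal(ens: ConformerEnsemble,
                           model_index: int | None = None
                           ) -> list[ResidueAnnotation]:
    """Kabsch–Sander H-bonds and coarse secondary structure from geometry.

    Works on a single model (by default the first; pass the
    representative-model index for production use). A donor N-H of
    residue i and acceptor C=O of residue j (|i−j| ≥ 2) are bonded when
    the electrostatic energy is below −0.5 kcal/mol. Prolines would be
    excluded as donors; the toy ensembles generated here carry no
    sequence, so every residue with a reconstructed H may donate.

    Helices are residues covered by two consecutive i→i+4 turns;
    strands are residues in parallel or antiparallel bridges.
    """
    if ens.backbone_coords is None:
        raise AnnotationError("backbone N/C/O coordinates required for "
                              "internal H-bond assignment")
    k = 0 if model_index is None else model_index
    N = ens.backbone_coords["N"][k]
    C = ens.backbone_coords["C"][k]
    O = ens.backbone_coords["O"][k]
    n = N.shape[0]
    H = _reconstruct_amide_h(N, C, O)

    proline = {idx for idx, (_, _, aa) in enumerate(ens.residue_ids)
               if aa.upper() == "PRO"}
    donates: set[tuple[int, int]] = set()  # (donor i, acceptor j)
    for i in range(n):
        if i in proline or np.any(np.isnan(H[i])):
            continue
        for j in range(n):
            if abs(i - j) < 2:
                continue
            if _ks_energy(N[i], H[i], C[j], O[j]) < HBOND_ENERGY_CUTOFF:
                donates.add((i, j))

    anns = [ResidueAnnotation(source="internal") for _ in range(n)]
    for i, j in donates:
        anns[i].hbond_partners.add(j)
        anns[j].hbond_partners.add(i)

    # helix: residues i+1..i+4 of two consecutive 4-turns (turn at i when
    # the N-H of i+4 donates to the C=O of i)
    turn4 = {i for i in range(n - 4) if (i + 4, i) in donates}
    for i in turn4:
        if i - 1 in turn4 or i + 1 in turn4:
            for r in range(i + 1, i + 5):
                anns[r].ss_code = "H"

    # bridges (parallel or antiparallel) mark both partners as strand
    def hb(a, b):
        return (a, b) in donates

    for i in range(1, n - 1):
        for j in range(i + 2, n - 1):
            parallel = (hb(j, i - 1) and hb(i + 1, j)) or \
                       (hb(i, j - 1) and hb(j + 1, i))
            antiparallel = (hb(i, j) and hb(j, i)) or \
                           (hb(j + 1, i - 1) and hb(i + 1, j - 1))
            if parallel or antiparallel:
                if anns[i].ss_code != "H":
                    anns[i].ss_code = "E"
                if anns[j].ss_code != "H":
                    anns[j].ss_code = "E"
    return anns


def annotation_table(anns: list[ResidueAnnotation]) -> str:
    """Tab-separated annotation dump (1-based index, ss, partners)."""
    lines = ["index\tss\tpartners"]
    for i, a in enumerate(anns):
        partners = ",".join(str(p + 1) for p in sorted(a.hbond_partners))
        lines.append(f"{i + 1}\t{a.ss_code}\t{partners or '-'}")
    return "\n".join(lines) + "\n"
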