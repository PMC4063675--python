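"""File formats: pedigree TSV, IBD match files, sample lists, manifests.

Coordinates are physical Mbp, 0-based half-open, throughout the package;
files use the same convention.  The pedigree TSV is one row per individual
— ``id  father_id  mother_id  sex  generation`` — with ``0`` for a missing
parent and sex coded 1 (male) / 2 (female) / 0 (unknown); the first four
columns follow the PLINK .fam layout (family column omitted).  The IBD
match file is a tab-separated subset of the GERMLINE match dialect:
``id1  id2  chromosome  start_mbp  end_mbp  length_cm`` (extra trailing
columns tolerated).
"""

from __future__ import annotations

import json
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from pedrecon.genome import IBDFeatures, IBDSegment, ibd_features
from pedrecon.pedigree import FEMALE, MALE, UNKNOWN, Individual, Pedigree

_SEX_CODE = {MALE: "1", FEMALE: "2", UNKNOWN: "0"}
_CODE_SEX = {v: k for k, v in _SEX_CODE.items()}


def write_pedigree(P: Pedigree, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tfather_id\tmother_id\tsex\tgeneration\n")
        for ind in P.individuals.values():
            gen = "NA" if ind.generation is None else str(ind.generation)
            fh.write("\t".join([
                ind.id,
                ind.father_id or "0",
                ind.mother_id or "0",
                _SEX_CODE[ind.sex],
                gen,
            ]) + "\n")


def read_pedigree(path) -> Pedigree:
    """Read and validate a pedigree TSV (acyclic, known parents)."""
    P = Pedigree()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if ln == 1 and line.split("\t")[0] == "id":
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{ln}: expected 5 columns, got {len(parts)}")
            iid, fa, mo, sex, gen = parts[:5]
            if sex not in _CODE_SEX:
                raise ValueError(f"{path}:{ln}: bad sex code {sex!r}")
            generation = None if gen == "NA" else int(gen)
            P.add(Individual(
                iid,
                sex=_CODE_SEX[sex],
                generation=generation,
                father_id=None if fa == "0" else fa,
                mother_id=None if mo == "0" else mo,
                extant=(generation == 0),
            ))
    P.validate()
    return P


def write_samples(ids: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(i + "\n")


def read_samples(path) -> List[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_ibd_match(segments: Mapping[Tuple[str, str], Sequence[IBDSegment]],
                    path, cm_per_mbp: float = 1.0) -> None:
    with open(path, "w") as fh:
        for (a, b) in sorted(segments):
            for s in segments[(a, b)]:
                length_cm = s.length_mbp * cm_per_mbp
                fh.write(f"{a}\t{b}\t{s.chromosome}\t{s.start_mbp:.6f}\t"
                         f"{s.end_mbp:.6f}\t{length_cm:.6f}\n")


def read_ibd_match(path, samples: Optional[Sequence[str]] = None,
                   ) -> Dict[Tuple[str, str], List[IBDSegment]]:
    """Parse an IBD match file into sorted-pair keyed segment lists.

    Malformed rows are rejected with their line number; with a sample list
    given, unknown ids are reported collectively.
    """
    known = set(samples) if samples is not None else None
    unknown = set()
    out: Dict[Tuple[str, str], List[IBDSegment]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected >= 6 columns, got {len(parts)}")
            a, b, chrom = parts[0], parts[1], parts[2]
            try:
                start, end = float(parts[3]), float(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric coordinates") from exc
            if a == b:
                raise ValueError(f"{path}:{ln}: segment between identical ids {a!r}")
            if end <= start:
                raise ValueError(f"{path}:{ln}: end <= start")
            if known is not None:
                unknown.update(x for x in (a, b) if x not in known)
            key = (a, b) if a < b else (b, a)
            out.setdefault(key, []).append(IBDSegment(chrom, start, end))
    if unknown:
        raise ValueError(f"{path}: unknown sample ids: {', '.join(sorted(unknown))}")
    return out


def features_from_match(segments: Mapping[Tuple[str, str], Sequence[IBDSegment]],
                        ) -> Dict[Tuple[str, str], IBDFeatures]:
    return {pair: ibd_features(segs) for pair, segs in segments.items()}


def write_manifest(path, **fields) -> None:
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
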