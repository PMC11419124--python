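"""Independent brute-force oracles for the deduplication stages.

These deliberately share no code with the package: stages 3–5 are
re-derived from their definitions via exhaustive pairwise scans, for
cross-checking the cascade on small record sets.
"""

from __future__ import annotations

import math

from rdkit import Chem


def _norm_authors(authors):
    return frozenset(" ".join(a.split()).casefold() for a in authors if a.strip())


def _system(r):
    return (r.uniprot_id, Chem.MolToSmiles(Chem.MolFromSmiles(r.smiles)))


def _rank(r):
    return (r.year if r.year is not None else math.inf, r.index)


def brute_force_within_document(records):
    """Keep argmax-p per (system, document) by scanning all pairs."""
    keep = []
    for r in records:
        beaten = any(
            s is not r
            and _system(s) == _system(r)
            and s.document_id == r.document_id
            and (s.pvalue, -s.index) > (r.pvalue, -r.index)
            for s in records
        )
        if not beaten:
            keep.append(r)
    return keep


def brute_force_citation_dedup(records, tolerance=1e-6):
    """Connected components of the |Δp| ≤ tol relation; earliest survives."""
    keep = []
    for r in records:
        # grow r's identical-value component by repeated pairwise expansion
        component = {id(r): r}
        changed = True
        while changed:
            changed = False
            for s in records:
                if id(s) in component or _system(s) != _system(r):
                    continue
                if any(abs(s.pvalue - t.pvalue) <= tolerance for t in component.values()):
                    component[id(s)] = s
                    changed = True
        if min(component.values(), key=_rank) is r:
            keep.append(r)
    return keep


def brute_force_author_overlap(records):
    """Connected components of author-set intersection; earliest survives."""
    keep = []
    for r in records:
        component = {id(r): r}
        changed = True
        while changed:
            changed = False
            for s in records:
                if id(s) in component or _system(s) != _system(r):
                    continue
                sa = _norm_authors(s.authors)
                if sa and any(
                    sa & _norm_authors(t.authors) for t in component.values()
                ):
                    component[id(s)] = s
                    changed = True
        if min(component.values(), key=_rank) is r:
            keep.append(r)
    return keep


def brute_force_dedup_stages(records, tolerance=1e-6):
    """Stages 3–5 composed, each by exhaustive pairwise scan."""
    out = brute_force_within_document(records)
    out = brute_force_citation_dedup(out, tolerance)
    return brute_force_author_overlap(out)
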