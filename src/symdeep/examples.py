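"""Worked-example fixtures mirroring the published dilution-series study.

The reference-library example reproduces the structure of the study's
annotated library: 28 references (17 A13, four C1, three C3, four D1,
labelled with the study's letter suffixes), mapped-read counts over the
15-sample dilution design in which reference A13(i) is absent from the
85 % A13 sample and C1(g) is absent from the 97 % C1 sample — the two
references the known-dominant pruning rule must eliminate.
"""

from __future__ import annotations

import numpy as np

from .cluster import ReferenceSet
from .mapping import TypeAnnotation
from .simulate import dilution_series_designs

A13_SUFFIXES = "cijklmnopqstuvw"  # 15 single-letter A13 references
A13_EXTRA = ("zz", "zzz")  # plus the two long-suffix ones: 17 in total
C1_SUFFIXES = "bfgr"
C3_SUFFIXES = "ehx"
D1_SUFFIXES = "adyz"

ABSENT = {
    "A13(i)": "S09",  # zero reads in the 85 % A13 sample
    "C1(g)": "S07",  # zero reads in the 97 % C1 sample
}


def reference_library_ids() -> dict[str, str]:
    """reference_id -> type_name for the 28-entry annotated library."""
    ids = {f"A13({s})": "A13" for s in A13_SUFFIXES}
    ids.update({f"A13({s})": "A13" for s in A13_EXTRA})
    ids.update({f"C1({s})": "C1" for s in C1_SUFFIXES})
    ids.update({f"C3({s})": "C3" for s in C3_SUFFIXES})
    ids.update({f"D1({s})": "D1" for s in D1_SUFFIXES})
    return ids


def reference_library_example(seed: int = 0):
    """The 28-reference pruning example.

    Returns ``(reference_set, annotations, counts, designs)`` ready for
    :func:`symdeep.mapping.prune_references`: counts give every reference
    non-zero reads in each high-abundance (>= 85 %) sample of its type,
    except the two absences listed in :data:`ABSENT`.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    type_of = reference_library_ids()
    references = []
    annotations = []
    for i, (ref_id, type_name) in enumerate(type_of.items()):
        bases = "".join(rng.choice(list("ACGT"), 300))
        references.append((ref_id, bases, 500 - i))
        annotations.append(TypeAnnotation(ref_id, type_name, 100.0))
    reference_set = ReferenceSet(references)

    designs = {
        d.sample_id: dict(d.cell_fractions) for d in dilution_series_designs()
    }
    counts = pd.DataFrame(
        0, index=sorted(designs), columns=list(type_of), dtype=int
    )
    for sample_id, fractions in designs.items():
        for ref_id, type_name in type_of.items():
            fraction = fractions.get(type_name, 0.0)
            if fraction <= 0.0:
                continue
            if ABSENT.get(ref_id) == sample_id:
                continue
            counts.loc[sample_id, ref_id] = max(
                1, int(round(10_000 * fraction / 4))
            )
    return reference_set, annotations, counts, designs
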