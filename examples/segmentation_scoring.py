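"""Prototype construction and the two segmentation scores, by hand.

Three reference participants press boundaries on the normalized
timeline; pooled presses are clustered into prototypical boundaries
ranked by how many distinct participants contributed.  A test
participant is then scored: typicality (mean frequency of matched
prototypes; unmatched presses score 0) and temporal accuracy (mean
absolute deviation from matched prototype positions, in % of the
timeline; higher = worse).
"""

from walkmem import (
    BoundaryCategory,
    NormalizedBoundary,
    build_prototypes,
    temporal_accuracy_score,
    typicality_score,
)


def presses(pid, *positions):
    return [NormalizedBoundary(pid, p, BoundaryCategory.PERCEPTUAL) for p in positions]


reference = {
    "ref_a": presses("ref_a", 0.10, 0.50),
    "ref_b": presses("ref_b", 0.11, 0.52),
    "ref_c": presses("ref_c", 0.90),
}
prototypes = build_prototypes(reference, w=0.02, top_k=3)
for p in prototypes:
    print(f"{p.prototype_id}: position {p.position:.3f}, "
          f"{p.frequency}/3 reference participants")

subject = presses("subj", 0.105, 0.53, 0.30)  # last press matches nothing
typ = typicality_score(subject, prototypes, w=0.02)
acc = temporal_accuracy_score(subject, prototypes, w=0.02)
print(f"\ntypicality       = {typ:.3f}  (mean of matched frequencies 2, 2 "
      "and an unmatched 0)")
print(f"temporal accuracy = {acc:.3f} percentage points of the timeline")
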