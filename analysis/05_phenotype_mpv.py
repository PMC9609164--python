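#!/usr/bin/env python
"""Multilocus pathogenic variation (MPV) search on a toy ontology.

Demonstrates the quantitative phenotyping chain — information content,
Lin set similarity and the k-gene combination search with the >5%
relative-improvement rule — on a two-branch toy ontology where the
proband's phenotype genuinely spans two genes: the dual-gene model
improves the best single-gene similarity by ~6% (flagged as MPV) while
a third gene adds only ~1-2% (not flagged).

Writes results/mpv_search.tsv.
"""

from pathlib import Path

from perizygote import phenotype_similarity as ps

OUT = Path(__file__).resolve().parents[1] / "results"


def build_fixture():
    parents = {
        "R": [], "u": ["R"], "v": ["R"],
        "p1": ["u"], "g1": ["u"], "g3": ["u"],
        "p2": ["v"], "g2": ["v"], "x1": ["v"], "x2": ["R"],
    }
    onto = ps.OntologyGraph(parents)
    counts = {"p1": 4, "g1": 4, "g3": 2, "p2": 4, "g2": 4, "x1": 10, "x2": 14}
    annotations = {}
    i = 0
    for term, k in counts.items():
        for _ in range(k):
            annotations[f"e{i}"] = [term]
            i += 1
    return ps.AnnotationCorpus(onto, annotations)


def main() -> None:
    corpus = build_fixture()
    proband = ["p1", "p2"]
    genes = {"G1": ["g1"], "G2": ["g2"], "G3": ["g3"]}
    result = ps.mpv_search(proband, genes, corpus, k_max=3)
    print(result.per_k.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    flagged = result.per_k[result.per_k["mpv_flag"]]
    if len(flagged):
        row = flagged.iloc[-1]
        print(
            f"MPV candidate: {row['genes']} at k={row['k']} "
            f"(+{100 * row['improvement']:.1f}% over the best k-1 model)"
        )
    OUT.mkdir(exist_ok=True)
    result.per_k.to_csv(OUT / "mpv_search.tsv", sep="\t", index=False)
    print(f"wrote {OUT / 'mpv_search.tsv'}")


if __name__ == "__main__":
    main()
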