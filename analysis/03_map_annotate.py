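"""Map unique reads without mismatches and classify them into sRNA types.

Writes the class x length composition matrices (unique-read and
count-weighted) per cultivar, plus the derived siRNA superclass row.
"""
from pathlib import Path

from srnacompare.annotation import (
    ClassPrecedence,
    FeatureIndex,
    classify_all,
    composition_by_length,
    sirna_fraction,
)
from srnacompare.mapping import build_index, map_exact
from srnacompare.preprocess import preprocess_reads
from srnacompare.simulate import SyntheticSpec, generate_experiment
from srnacompare.types import TrimParams

SEED = 42

if __name__ == "__main__":
    exp = generate_experiment(SyntheticSpec(), seed=SEED)
    params = TrimParams(adapter=exp.spec.adapter)
    index = build_index(exp.genome, k=15)
    findex = FeatureIndex(exp.features, chloroplast_chroms=[exp.spec.chloroplast_name])
    Path("results").mkdir(exist_ok=True)

    for cultivar, reads in (("A", exp.reads_a), ("B", exp.reads_b)):
        unique, _ = preprocess_reads(reads, params)
        hits = map_exact(unique, index)
        n_mapped = sum(1 for h in hits.values() if h)
        print(f"cultivar {cultivar}: {n_mapped}/{len(unique)} unique reads mapped")
        classes = classify_all(hits, findex, ClassPrecedence())
        comps = composition_by_length(classes, unique, sorted(exp.spec.length_dist))
        for weighting, mat in comps.items():
            mat.loc["siRNA (derived)"] = sirna_fraction(mat)
            path = f"results/composition_{cultivar}_{weighting}.tsv"
            mat.to_csv(path, sep="\t", float_format="%.6g")
        print(comps["count"].loc[["miRNA", "repeat", "chloroplast"], [20, 21, 24]])
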