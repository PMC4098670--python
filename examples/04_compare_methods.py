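"""Compare SOM day types with k-means and Ward clustering partitions.

Agreement is the percent of days on which two partitions coincide after
optimally matching their class identities (Hungarian matching on the
confusion matrix). The SOM is expected to behave like a topology-
constrained k-means, so SOM-vs-k-means agreement is typically the highest.
"""

from airsom import (
    SOMGrid,
    TrainingSchedule,
    agreement,
    codebook_sammon,
    complete_case_filter,
    generate,
    kmeans,
    standardize,
    table1_profile,
    train_with_restarts,
    ward_clustering,
)

Z, _ = generate(table1_profile(seed=4))
Zc = complete_case_filter(Z)
Zs, _ = standardize(Zc)
model = train_with_restarts(
    Zs.values, SOMGrid(4, 4), TrainingSchedule(seed=4), n_restarts=10
)
km = kmeans(Zs.values, 16, n_restarts=10, seed=4)
ward_labels, _ = ward_clustering(Zs.values, 16)

print(f"SOM vs k-means: {agreement(model.assignments, km.labels):5.1f}% of days")
print(f"SOM vs Ward:    {agreement(model.assignments, ward_labels):5.1f}%")
print(f"k-means vs Ward:{agreement(km.labels, ward_labels):6.1f}%")
print("High agreement means the SOM found partitions comparable to "
      "conventional clustering while adding the organized map.")

coords, stress = codebook_sammon(model, seed=4)
print(f"\nSammon projection of the 16 class profiles: stress = {stress:.4f}")
print("(low stress: inter-class dissimilarities are displayed faithfully; "
      "the projection reveals where the finite grid distorts them)")
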