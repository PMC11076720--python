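"""Case-based retrieval: nearest solved cases in normalized feature space.

A synthetic library stands in for the hospital case base; the query is one
of its own sessions, so the nearest case is itself at distance zero.
"""

from rehabdss import GenerationSpec, generate_case_library

lib = generate_case_library(
    GenerationSpec(n_patients=30, sessions_per_patient=5, samples_per_session=300, seed=4)
)
print(f"library: {len(lib)} cases, per mode "
      + ", ".join(f"{m.value}={n}" for m, n in lib.modes().items()))

query_case = lib.partition("assisted")[10]
neighbours = lib.retrieve_similar(query_case.features, "assisted", k=5)
print(f"query: case {query_case.case_id} (level_up={query_case.level_up})")
print("nearest assisted-mode cases (min-max-normalized Euclidean distance):")
for case, dist in neighbours:
    print(f"  {case.case_id}  distance {dist:.3f}  level_up={case.level_up}")
print("distance 0.000 for the first hit confirms self-retrieval.")
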