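"""Why random or equal transition probabilities fail to explain the data.

Under neighbour-adoption dynamics with random (or uniform 1/3) transition
probabilities, a site can only be converted into a copy of an adjacent
site.  Such runs do end — but in homogeneous endplates: everything one
axon, all tSC, or all vacant.  None of these reproduce the observed
endpoint of development, where a single axon coexists with tSCs and
vacancies; that state is only reached by the vacancy-mediated chain with
probabilities solved from the measured compositions.

Uses a 30-site endplate in a smaller disc (which keeps the contact graph
connected) so each run finishes in seconds.
"""

from endplatesim import RunConfig, build_layout, run
from endplatesim.config import CompositionConfig, GeometryConfig

config = RunConfig(
    geometry=GeometryConfig(n_sites=30, region_diameter=170.0),
    composition=CompositionConfig(n_axons=4),
)

for model in ("random", "equal"):
    print(f"{model} transition probabilities:")
    for seed in range(6):
        layout = build_layout(config, seed=seed)
        result = run(layout, model=model, seed=100 + seed, max_iter=500_000)
        label = (
            f"single axon {result.winner} (no tSCs or vacancies left)"
            if isinstance(result.winner, int)
            else result.winner.replace("_", " ").lower()
        )
        print(f"  seed {seed}: {label} after {result.iterations} iterations")
    print()
print(
    "Every terminal state is homogeneous - the stable co-presence of one"
    "\naxon with tSCs and vacancies never occurs under these dynamics."
)
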