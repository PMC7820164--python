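"""Generate synthetic stem maps for the two stand conditions and summarize them.

The historical preset emulates a frequent-fire mixed-conifer stand:
moderate density, clustered trees, size segregation, sparse dispersed
large trees.  The contemporary preset emulates a fire-excluded stand:
roughly double the density, weak clustering, intermixed sizes, low crowns.
"""

from firestand import PlotWindow, generate_forest, preset_config, summarize_structure

window = PlotWindow(0, 200, 0, 215)  # 4.3 ha, the size of a classic mapped plot

for era in ("historical", "contemporary"):
    stand = generate_forest(preset_config(era, window, seed=7))
    s = summarize_structure(stand)
    print(f"{era:13s}  n={s.n_trees:5d}  tph={s.tph:6.1f}  "
          f"ba={s.ba:5.1f} m2/ha  qmd={s.qmd:5.1f} cm  cbh10={s.cbh10:4.2f} m")

# tph is stem density; ba basal area; qmd the quadratic mean diameter;
# cbh10 the tenth-percentile crown base height (stand canopy base height).
# The historical stand should be sparser with larger trees and higher
# crowns than the contemporary one.
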