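# Whittaker biome polygons in (MAT degC, MAP mm/yr) space.
#
# The nine classic biomes, digitized by this package as straight-edge
# polygons approximating the familiar MAT x MAP diagram (temperature on the
# horizontal axis, precipitation on the vertical axis, bounded above by a
# maximum-precipitation line rising from (-15 degC, 0 mm) to (30 degC,
# 4500 mm)).  This file is replaceable data, not code: supply your own
# vertex set to change the classification.  Order matters: a point on a
# shared edge is assigned to the polygon listed first.
biomes:
  - name: tundra
    vertices:
      - [-15, 0]
      - [-5, 0]
      - [-5, 1000]
  - name: boreal forest
    vertices:
      - [-5, 0]
      - [5, 0]
      - [5, 2000]
      - [-5, 1000]
  - name: temperate seasonal forest
    vertices:
      - [5, 900]
      - [20, 900]
      - [20, 2200]
      - [7, 2200]
      - [5, 2000]
  - name: temperate rain forest
    vertices:
      - [7, 2200]
      - [20, 2200]
      - [20, 3500]
  - name: tropical rain forest
    vertices:
      - [20, 2400]
      - [30, 2400]
      - [30, 4500]
      - [20, 3500]
  - name: tropical seasonal forest/savanna
    vertices:
      - [20, 400]
      - [30, 400]
      - [30, 2400]
      - [20, 2400]
  - name: subtropical desert
    vertices:
      - [20, 0]
      - [30, 0]
      - [30, 400]
      - [20, 400]
  - name: temperate grassland/desert
    vertices:
      - [5, 0]
      - [20, 0]
      - [20, 400]
      - [5, 400]
  - name: woodland/shrubland
    vertices:
      - [5, 400]
      - [20, 400]
      - [20, 900]
      - [5, 900]
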