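# 2017 Sante publique France / FSA-Ofcom nutrient-profiling thresholds used
# by the NutriScore front-of-pack label.  All values are per 100 g (or 100 mL
# for beverages).  Penalty components score one point per threshold strictly
# exceeded (0-10); reward components likewise (0-5), except the
# fruit/vegetable/nut/oil (fvno) component which uses its own point ladder.
# Edit this file to explore alternative table revisions.
components:
  general:
    energy_kj: [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350]
    saturated_fat_g: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
    sugars_g: [4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45]
    sodium_mg: [90, 180, 270, 360, 450, 540, 630, 720, 810, 900]
    fiber_g: [0.9, 1.9, 2.8, 3.7, 4.7]
    protein_g: [1.6, 3.2, 4.8, 6.4, 8.0]
    fvno:
      thresholds: [40, 60, 80]
      points: [1, 2, 5]
  beverage:
    energy_kj: [0, 30, 60, 90, 120, 150, 180, 210, 240, 270]
    sugars_g: [0, 1.5, 3, 4.5, 6, 7.5, 9, 10.5, 12, 13.5]
    fvno:
      thresholds: [40, 60, 80]
      points: [2, 4, 10]
  added_fat:
    # saturated fat : total fat ratio, in percent
    saturated_fat_ratio_percent: [10, 16, 22, 28, 34, 40, 46, 52, 58, 64]
# Protein points are not counted when the negative sum reaches the threshold
# unless the fvno component is at its exemption level; cheese is exempt from
# the cap entirely.
protein_cap:
  negative_threshold: 11
  fvno_exemption_points:
    general: 5
    beverage: 10
  cheese_exempt: true
# Letter cut-points on the total (inclusive ranges).  Cheese and added fats
# use the general cut-points.  Beverages other than plain water cannot score
# A; plain water is classed A by definition.
letters:
  general:
    A: [-100, -1]
    B: [0, 2]
    C: [3, 10]
    D: [11, 18]
    E: [19, 100]
  beverage:
    B: [-100, 1]
    C: [2, 5]
    D: [6, 9]
    E: [10, 100]
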