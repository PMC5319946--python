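# Anxiety rating scale for rats: four items, total 0-28 points.
# ID%, IT% and OT% share one bin structure; OE% has a wide 1-point bin
# covering 1-20%.
items:
  id_pct:
    units: percent
    max_points: 7
    domain: {lo: 0.0, hi: 100.0}
    bins:
      - {lo: 0.0,  hi: 1.0,  points: 0}
      - {lo: 1.0,  hi: 5.0,  points: 1}
      - {lo: 5.0,  hi: 10.0, points: 2}
      - {lo: 10.0, hi: 15.0, points: 3}
      - {lo: 15.0, hi: 20.0, points: 4}
      - {lo: 20.0, hi: 25.0, points: 5}
      - {lo: 25.0, hi: 30.0, points: 6}
      - {lo: 30.0, hi: 100.0, hi_closed: true, points: 7}
  it_pct:
    units: percent
    max_points: 7
    domain: {lo: 0.0, hi: 100.0}
    bins:
      - {lo: 0.0,  hi: 1.0,  points: 0}
      - {lo: 1.0,  hi: 5.0,  points: 1}
      - {lo: 5.0,  hi: 10.0, points: 2}
      - {lo: 10.0, hi: 15.0, points: 3}
      - {lo: 15.0, hi: 20.0, points: 4}
      - {lo: 20.0, hi: 25.0, points: 5}
      - {lo: 25.0, hi: 30.0, points: 6}
      - {lo: 30.0, hi: 100.0, hi_closed: true, points: 7}
  ot_pct:
    units: percent
    max_points: 7
    domain: {lo: 0.0, hi: 100.0}
    bins:
      - {lo: 0.0,  hi: 1.0,  points: 0}
      - {lo: 1.0,  hi: 5.0,  points: 1}
      - {lo: 5.0,  hi: 10.0, points: 2}
      - {lo: 10.0, hi: 15.0, points: 3}
      - {lo: 15.0, hi: 20.0, points: 4}
      - {lo: 20.0, hi: 25.0, points: 5}
      - {lo: 25.0, hi: 30.0, points: 6}
      - {lo: 30.0, hi: 100.0, hi_closed: true, points: 7}
  oe_pct:
    units: percent
    max_points: 7
    domain: {lo: 0.0, hi: 100.0}
    bins:
      - {lo: 0.0,  hi: 1.0,  points: 0}
      - {lo: 1.0,  hi: 20.0, points: 1}
      - {lo: 20.0, hi: 25.0, points: 2}
      - {lo: 25.0, hi: 30.0, points: 3}
      - {lo: 30.0, hi: 35.0, points: 4}
      - {lo: 35.0, hi: 40.0, points: 5}
      - {lo: 40.0, hi: 45.0, points: 6}
      - {lo: 45.0, hi: 100.0, hi_closed: true, points: 7}
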