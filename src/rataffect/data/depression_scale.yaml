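# Depression rating scale for rats: four items, total 0-25 points.
# Bins are lower-closed / upper-open unless flagged otherwise; hi: null
# means unbounded above.  Edit freely and re-run `rataffect validate-scales`.
items:
  weight:
    units: g
    max_points: 5
    domain: {lo: 0.0, hi: null}
    bins:
      - {lo: 0.0,   hi: 300.0, points: 1}
      - {lo: 300.0, hi: 310.0, points: 2}
      - {lo: 310.0, hi: 320.0, points: 3}
      - {lo: 320.0, hi: 330.0, points: 4}
      - {lo: 330.0, hi: 340.0, points: 5}
      - {lo: 340.0, hi: 350.0, points: 5}
      - {lo: 350.0, hi: 360.0, points: 5}
      - {lo: 360.0, hi: 370.0, points: 4}
      - {lo: 370.0, hi: 380.0, points: 3}
      - {lo: 380.0, hi: 390.0, points: 2}
      - {lo: 390.0, hi: null,  points: 1}
  sucrose:
    units: percent
    max_points: 10
    domain: {lo: 0.0, hi: 100.0}
    bins:
      - {lo: 0.0,  hi: 50.0, points: 0}
      - {lo: 50.0, hi: 55.0, points: 1}
      - {lo: 55.0, hi: 60.0, points: 2}
      - {lo: 60.0, hi: 65.0, points: 3}
      - {lo: 65.0, hi: 70.0, points: 4}
      - {lo: 70.0, hi: 75.0, points: 5}
      - {lo: 75.0, hi: 80.0, points: 6}
      - {lo: 80.0, hi: 85.0, points: 7}
      - {lo: 85.0, hi: 90.0, points: 8}
      - {lo: 90.0, hi: 95.0, points: 9}
      - {lo: 95.0, hi: 100.0, hi_closed: true, points: 10}
  distance:
    units: m
    max_points: 5
    domain: {lo: 0.0, hi: null}
    bins:
      # exactly 0 m (no movement) scores 0; any movement below 5 m scores 1
      - {lo: 0.0,  hi: 0.0, hi_closed: true, points: 0}
      - {lo: 0.0,  hi: 5.0, lo_closed: false, points: 1}
      - {lo: 5.0,  hi: 10.0, points: 2}
      - {lo: 10.0, hi: 15.0, points: 3}
      - {lo: 15.0, hi: 20.0, points: 4}
      - {lo: 20.0, hi: null, points: 5}
  rearing:
    units: count
    max_points: 5
    domain: {lo: 0.0, hi: null}
    bins:
      - {lo: 0.0,  hi: 0.0, hi_closed: true, points: 0}
      - {lo: 0.0,  hi: 5.0, lo_closed: false, points: 1}
      - {lo: 5.0,  hi: 10.0, points: 2}
      - {lo: 10.0, hi: 15.0, points: 3}
      - {lo: 15.0, hi: 20.0, points: 4}
      - {lo: 20.0, hi: null, points: 5}
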