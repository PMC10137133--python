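# Reference three-arm platform-trial design: non-concurrent controls accrue
# on [0, 3]; the concurrent controls and the new treatment accrue on [3, 6];
# the control hazard drops from 0.2 to 0.2*exp(-0.4) ~= 0.134 when the new
# arm enters at calendar time 3; administrative censoring at time 15.
arms:
  - name: ncc_control
    n: 100
    accrual: [0.0, 3.0]
    hazard:
      breakpoints: [3.0]
      rates: [0.2, 0.134064009207128]   # 0.2 * exp(-0.4)
  - name: cc_control
    n: 100
    accrual: [3.0, 6.0]
    hazard:
      rates: [0.134064009207128]
  - name: treatment
    n: 100
    accrual: [3.0, 6.0]
    hazard:
      rates: [0.114]
t1_entry: 3.0
t_max: 15.0
seed: 20230331
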