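# Default bed layout: 5 sectors (regions), 10 sensor nodes, 2 per sector.
regions: [r1, r2, r3, r4, r5]
nodes:
  n1:  {region: r1, sensor: "Pressure sensors (head)"}
  n2:  {region: r1, sensor: "Infrared sensors"}
  n3:  {region: r2, sensor: "Movement sensors"}
  n4:  {region: r2, sensor: "Noise sensor"}
  n5:  {region: r3, sensor: "Weight sensors"}
  n6:  {region: r3, sensor: "Bed exit sensor"}
  n7:  {region: r4, sensor: "Pressure sensors (back)"}
  n8:  {region: r4, sensor: "Pressure sensors (feet)"}
  n9:  {region: r5, sensor: "Breathing rate sensors"}
  n10: {region: r5, sensor: "Heart rate sensors"}
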