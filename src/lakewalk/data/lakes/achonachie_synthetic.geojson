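{"type": "FeatureCollection", "metadata": {"lake": "Achonachie", "synthetic": true, "approximate": true, "note": "constructed stand-in shoreline; coarse aspect only, area normalized on load", "crs": "planar meters, centroid origin"}, "features": [{"type": "Feature", "properties": {"role": "lake"}, "geometry": {"type": "Polygon", "coordinates": [[[792.3, 0.0], [783.7, 11.8], [773.9, 23.4], [763.1, 34.7], [751.3, 45.8], [738.7, 56.5], [725.4, 67.0], [711.4, 77.2], [696.9, 87.1], [682.0, 96.8], [666.6, 106.2], [650.8, 115.4], [634.7, 124.4], [618.3, 133.2], [601.5, 141.8], [584.5, 150.2], [567.1, 158.5], [549.4, 166.6], [531.3, 174.5], [512.7, 182.3], [493.8, 189.9], [474.4, 197.4], [454.4, 204.6], [434.0, 211.7], [412.9, 218.6], [391.2, 225.2], [369.0, 231.6], [346.1, 237.7], [322.5, 243.5], [298.4, 248.9], [273.6, 254.0], [248.2, 258.8], [222.2, 263.1], [195.8, 267.0], [168.8, 270.4], [141.4, 273.4], [113.6, 275.9], [85.5, 277.9], [57.2, 279.5], [28.7, 280.5], [0.0, 281.0], [-28.7, 281.1], [-57.4, 280.6], [-86.1, 279.7], [-114.6, 278.3], [-143.0, 276.4], [-171.1, 274.1], [-199.0, 271.4], [-226.6, 268.3], [-254.0, 264.8], [-281.0, 260.9], [-307.7, 256.7], [-334.0, 252.1], [-360.0, 247.2], [-385.7, 242.1], [-411.0, 236.6], [-435.9, 230.8], [-460.6, 224.7], [-484.8, 218.3], [-508.7, 211.7], [-532.3, 204.7], [-555.5, 197.5], [-578.2, 189.9], [-600.5, 182.1], [-622.3, 173.9], [-643.5, 165.4], [-664.2, 156.5], [-684.1, 147.4], [-703.3, 137.8], [-721.6, 128.0], [-739.0, 117.7], [-755.3, 107.2], [-770.5, 96.3], [-784.4, 85.1], [-796.9, 73.6], [-808.0, 61.8], [-817.4, 49.8], [-825.2, 37.6], [-831.2, 25.2], [-835.3, 12.6], [-837.5, 0.0], [-837.7, -12.7], [-835.9, -25.3], [-832.1, -37.9], [-826.2, -50.3], [-818.2, -62.6], [-808.2, -74.6], [-796.3, -86.4], [-782.4, -97.8], [-766.8, -108.8], [-749.4, -119.4], [-730.4, -129.5], [-709.9, -139.1], [-688.1, -148.2], [-665.1, -156.7], [-641.0, -164.7], [-616.0, -172.1], [-590.3, -179.0], [-564.0, -185.3], [-537.3, -191.0], [-510.3, -196.3], [-483.2, -201.0], [-456.0, -205.3], [-428.8, -209.2], [-401.9, -212.7], [-375.1, -215.9], [-348.6, -218.8], [-322.5, -221.5], [-296.7, -224.0], [-271.3, -226.3], [-246.1, -228.6], [-221.3, -230.7], [-196.7, -232.9], [-172.3, -235.0], [-148.1, -237.2], [-123.8, -239.4], [-99.5, -241.6], [-75.1, -243.9], [-50.4, -246.2], [-25.4, -248.6], [-0.0, -250.9], [25.9, -253.2], [52.3, -255.5], [79.3, -257.6], [106.9, -259.6], [135.2, -261.3], [164.1, -262.8], [193.6, -264.0], [223.7, -264.8], [254.4, -265.2], [285.5, -265.1], [317.0, -264.5], [348.7, -263.2], [380.6, -261.4], [412.4, -258.8], [444.1, -255.6], [475.4, -251.7], [506.3, -247.0], [536.4, -241.6], [565.7, -235.4], [594.0, -228.5], [621.1, -220.8], [646.9, -212.5], [671.2, -203.5], [693.8, -193.9], [714.7, -183.7], [733.7, -172.9], [750.8, -161.7], [765.9, -150.1], [778.9, -138.1], [789.8, -125.8], [798.7, -113.3], [805.5, -100.7], [810.2, -87.9], [813.0, -75.1], [813.8, -62.3], [812.8, -49.5], [810.0, -36.9], [805.6, -24.4], [799.7, -12.1], [792.3, 0.0]]]}}, {"type": "Feature", "properties": {"role": "start"}, "geometry": {"type": "Point", "coordinates": [-796.9, 73.6]}}, {"type": "Feature", "properties": {"role": "capture_center"}, "geometry": {"type": "Point", "coordinates": [725.4, 67.0]}}]}
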