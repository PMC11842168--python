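{"type": "FeatureCollection", "metadata": {"lake": "Meig", "synthetic": true, "approximate": true, "note": "constructed stand-in shoreline; coarse aspect only, area normalized on load", "crs": "planar meters, centroid origin"}, "features": [{"type": "Feature", "properties": {"role": "lake"}, "geometry": {"type": "Polygon", "coordinates": [[[632.5, 0.0], [629.5, 8.2], [625.9, 16.4], [621.7, 24.5], [616.9, 32.6], [611.5, 40.5], [605.6, 48.5], [599.0, 56.3], [591.8, 64.1], [583.9, 71.8], [575.3, 79.4], [566.0, 87.0], [556.0, 94.4], [545.3, 101.8], [533.7, 109.0], [521.3, 116.1], [508.1, 123.1], [494.1, 129.8], [479.3, 136.4], [463.6, 142.8], [447.1, 149.0], [429.8, 155.0], [411.7, 160.7], [392.8, 166.1], [373.3, 171.2], [353.0, 176.1], [332.1, 180.7], [310.6, 184.9], [288.6, 188.8], [266.1, 192.4], [243.2, 195.7], [219.8, 198.6], [196.2, 201.2], [172.2, 203.5], [148.0, 205.5], [123.7, 207.2], [99.1, 208.6], [74.5, 209.7], [49.7, 210.5], [24.9, 211.0], [0.0, 211.3], [-24.9, 211.3], [-49.8, 211.1], [-74.8, 210.6], [-99.7, 209.9], [-124.7, 208.9], [-149.6, 207.8], [-174.6, 206.3], [-199.5, 204.7], [-224.4, 202.8], [-249.3, 200.6], [-274.2, 198.2], [-298.9, 195.5], [-323.6, 192.6], [-348.1, 189.3], [-372.4, 185.8], [-396.5, 181.9], [-420.3, 177.7], [-443.8, 173.2], [-466.8, 168.3], [-489.2, 163.1], [-511.1, 157.5], [-532.3, 151.5], [-552.6, 145.2], [-572.1, 138.5], [-590.5, 131.5], [-607.9, 124.2], [-624.0, 116.5], [-638.9, 108.5], [-652.4, 100.3], [-664.4, 91.7], [-674.9, 83.0], [-683.7, 74.1], [-691.0, 65.0], [-696.5, 55.7], [-700.3, 46.4], [-702.4, 37.1], [-702.8, 27.7], [-701.5, 18.4], [-698.6, 9.1], [-694.0, 0.0], [-687.9, -9.0], [-680.3, -17.8], [-671.2, -26.5], [-661.0, -34.9], [-649.5, -43.1], [-636.9, -51.0], [-623.3, -58.6], [-608.9, -65.9], [-593.7, -73.0], [-578.0, -79.8], [-561.6, -86.3], [-544.9, -92.5], [-527.9, -98.5], [-510.6, -104.3], [-493.1, -109.8], [-475.6, -115.2], [-458.0, -120.3], [-440.3, -125.4], [-422.7, -130.3], [-405.2, -135.1], [-387.6, -139.8], [-370.0, -144.4], [-352.5, -149.0], [-334.8, -153.6], [-317.1, -158.2], [-299.2, -162.7], [-281.1, -167.3], [-262.6, -171.8], [-243.9, -176.3], [-224.7, -180.8], [-205.1, -185.3], [-184.9, -189.7], [-164.1, -193.9], [-142.7, -198.1], [-120.6, -202.1], [-97.9, -206.0], [-74.4, -209.6], [-50.3, -213.0], [-25.5, -216.0], [-0.0, -218.8], [26.1, -221.1], [52.7, -223.1], [79.7, -224.6], [107.2, -225.6], [135.0, -226.2], [162.9, -226.2], [191.0, -225.7], [219.0, -224.6], [246.8, -223.0], [274.3, -220.8], [301.5, -218.0], [328.1, -214.6], [354.0, -210.7], [379.2, -206.3], [403.5, -201.3], [426.8, -195.8], [449.1, -189.9], [470.2, -183.5], [490.1, -176.7], [508.8, -169.6], [526.1, -162.1], [542.2, -154.4], [556.9, -146.3], [570.2, -138.1], [582.3, -129.7], [593.0, -121.1], [602.4, -112.5], [610.6, -103.7], [617.7, -94.9], [623.6, -86.1], [628.4, -77.3], [632.2, -68.5], [635.0, -59.7], [636.9, -51.0], [638.0, -42.3], [638.3, -33.7], [637.9, -25.2], [636.7, -16.7], [634.9, -8.3], [632.5, 0.0]]]}}, {"type": "Feature", "properties": {"role": "start"}, "geometry": {"type": "Point", "coordinates": [-671.2, -26.5]}}, {"type": "Feature", "properties": {"role": "capture_center"}, "geometry": {"type": "Point", "coordinates": [638.0, -42.3]}}]}
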