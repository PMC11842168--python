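{"type": "FeatureCollection", "metadata": {"lake": "Bassenthwaite", "synthetic": true, "approximate": true, "note": "constructed stand-in shoreline; coarse aspect only, area normalized on load", "crs": "planar meters, centroid origin"}, "features": [{"type": "Feature", "properties": {"role": "lake"}, "geometry": {"type": "Polygon", "coordinates": [[[830.4, 0.0], [832.9, 91.6], [833.3, 183.6], [831.8, 275.7], [828.2, 367.3], [822.7, 458.2], [815.2, 548.0], [805.8, 636.4], [794.7, 723.0], [781.8, 807.6], [767.3, 889.9], [751.3, 969.7], [733.8, 1046.9], [715.0, 1121.2], [695.0, 1192.5], [673.9, 1260.8], [651.8, 1326.0], [628.9, 1388.1], [605.1, 1447.1], [580.7, 1503.0], [555.7, 1555.9], [530.1, 1605.8], [504.1, 1652.7], [477.7, 1696.8], [451.0, 1738.2], [424.0, 1776.9], [396.8, 1813.0], [369.3, 1846.6], [341.7, 1877.7], [313.9, 1906.4], [285.9, 1932.6], [257.8, 1956.5], [229.5, 1978.0], [201.2, 1997.0], [172.7, 2013.7], [144.1, 2027.8], [115.4, 2039.4], [86.6, 2048.3], [57.7, 2054.5], [28.9, 2057.9], [0.0, 2058.5], [-28.9, 2056.1], [-57.6, 2050.6], [-86.3, 2042.0], [-114.8, 2030.3], [-143.2, 2015.3], [-171.2, 1997.0], [-199.0, 1975.5], [-226.4, 1950.7], [-253.3, 1922.7], [-279.8, 1891.4], [-305.7, 1857.0], [-331.1, 1819.5], [-355.8, 1779.1], [-379.9, 1735.8], [-403.2, 1689.8], [-425.9, 1641.2], [-447.7, 1590.2], [-468.8, 1536.9], [-489.1, 1481.5], [-508.6, 1424.2], [-527.4, 1365.0], [-545.4, 1304.2], [-562.6, 1241.8], [-579.1, 1178.0], [-594.9, 1112.9], [-610.0, 1046.6], [-624.4, 979.1], [-638.2, 910.5], [-651.4, 840.8], [-664.0, 770.1], [-676.0, 698.3], [-687.5, 625.5], [-698.4, 551.5], [-708.7, 476.4], [-718.4, 400.1], [-727.5, 322.6], [-736.0, 243.9], [-743.8, 163.9], [-750.8, 82.6], [-757.0, 0.0], [-762.4, -83.9], [-766.8, -169.0], [-770.2, -255.2], [-772.5, -342.6], [-773.6, -430.8], [-773.4, -519.9], [-771.8, -609.5], [-768.8, -699.4], [-764.3, -789.5], [-758.1, -879.3], [-750.3, -968.6], [-740.9, -1057.0], [-729.6, -1144.1], [-716.6, -1229.6], [-701.8, -1313.1], [-685.3, -1394.1], [-667.0, -1472.3], [-647.0, -1547.3], [-625.4, -1618.7], [-602.2, -1686.1], [-577.5, -1749.2], [-551.4, -1807.8], [-524.1, -1861.4], [-495.6, -1910.0], [-466.1, -1953.4], [-435.8, -1991.3], [-404.8, -2023.8], [-373.2, -2050.8], [-341.2, -2072.3], [-309.0, -2088.5], [-276.6, -2099.4], [-244.3, -2105.3], [-212.2, -2106.3], [-180.3, -2102.7], [-148.8, -2094.8], [-117.8, -2083.0], [-87.4, -2067.6], [-57.6, -2049.0], [-28.4, -2027.5], [-0.0, -2003.5], [27.7, -1977.3], [54.8, -1949.5], [81.2, -1920.2], [106.9, -1889.7], [132.0, -1858.5], [156.6, -1826.6], [180.7, -1794.4], [204.5, -1761.9], [227.8, -1729.3], [251.0, -1696.6], [273.9, -1663.9], [296.8, -1631.1], [319.6, -1598.1], [342.5, -1564.9], [365.4, -1531.2], [388.4, -1496.9], [411.6, -1461.8], [434.9, -1425.6], [458.3, -1388.1], [481.8, -1349.0], [505.4, -1308.0], [529.0, -1265.0], [552.5, -1219.5], [575.9, -1171.5], [599.0, -1120.6], [621.8, -1066.8], [644.1, -1009.9], [665.7, -949.8], [686.7, -886.4], [706.7, -819.7], [725.8, -749.7], [743.6, -676.5], [760.2, -600.3], [775.4, -521.2], [789.0, -439.4], [800.9, -355.2], [811.1, -268.8], [819.5, -180.6], [825.9, -90.9], [830.4, 0.0]]]}}, {"type": "Feature", "properties": {"role": "start"}, "geometry": {"type": "Point", "coordinates": [86.6, 2048.3]}}, {"type": "Feature", "properties": {"role": "capture_center"}, "geometry": {"type": "Point", "coordinates": [-57.6, -2049.0]}}]}
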