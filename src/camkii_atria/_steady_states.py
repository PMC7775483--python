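"""Pre-equilibrated 1 Hz steady states for the named scenario presets.

Computed by pacing each preset to its limit behavior (ROS presets include
the oxidation-equilibration phase).  These serve as initial conditions so
steady-state protocols start close to equilibrium; the pacing criterion
still verifies them at run time.
"""

import numpy as np

STEADY_STATES = {
    "wt": np.array([-7.865435080399e+01, 5.609922201806e-03, 6.036842581783e-01, 6.037448203498e-01, 1.057673924876e-01, 9.083325100025e-06, 9.990429150033e-01, 9.999299041971e-01, 3.789717167005e-04, 9.998358151258e-01, 2.154870872192e-03, 9.798773318886e-01, 9.976041715341e-01, 2.725071124225e-06, 5.597147747206e-10, 1.197805586387e+01, 1.431005249173e+02, 4.193988527747e-02, 5.017228424142e-02, 3.104278337994e+02, 9.190154640180e+00, 3.845054067535e-01, 6.810762531855e-01, 1.829256345187e-01, 4.472226558912e-01, 8.198519838216e-01, 6.602707434938e-06, 1.373071542012e-02, 1.237429495036e-04, 1.343470380537e-02, 1.528522512962e-01, 0.000000000000e+00, 0.000000000000e+00, 9.993137108808e-01, 1.748218475355e-07, 8.548445333286e-13, 2.526997579573e-16, 7.396231254214e-13, 6.861142956156e-04, 0.000000000000e+00, 0.000000000000e+00, 3.058221288284e-03]),
    "oe": np.array([-7.798502117121e+01, 6.214603721991e-03, 5.770332318095e-01, 5.771809528818e-01, 2.357250307873e-01, 1.015524520293e-05, 9.989470595451e-01, 9.999942846120e-01, 4.027369009245e-04, 9.990824386501e-01, 2.278182186444e-03, 9.583415017953e-01, 9.990756152039e-01, 3.630965855324e-06, 1.062813607273e-10, 1.511790149778e+01, 1.399998514223e+02, 5.639859062647e-03, 1.436140694977e-02, 2.432782476735e+02, 1.304327006253e+00, 1.103369170786e-01, 9.827503669345e-01, 8.857395015211e-01, 5.902839048821e-01, 6.476865957569e-01, 1.176719107879e-07, 5.081766579785e-02, 1.813978867666e-03, 1.973365644356e-01, 1.023450774702e-01, 0.000000000000e+00, 0.000000000000e+00, 9.999764759364e-01, 5.818565400658e-11, 1.080923032990e-12, 7.482781326939e-18, 1.057531652933e-12, 2.352400336761e-05, 0.000000000000e+00, 0.000000000000e+00, 3.249006700280e-03]),
    "wt_ros": np.array([-7.871401874064e+01, 5.558945864606e-03, 6.060325552324e-01, 6.060798947002e-01, 1.082826439999e-01, 8.993447566921e-06, 9.990510287172e-01, 9.999952393017e-01, 3.769224961353e-04, 9.998374443308e-01, 2.144207564142e-03, 9.786285362860e-01, 9.994342111703e-01, 2.550628940658e-06, 6.544009912921e-11, 1.217130621661e+01, 1.429503769630e+02, 7.173668505025e-03, 1.310372228058e-02, 2.330953311224e+02, 1.654387473892e+00, 1.006867026901e-01, 9.744708421119e-01, 7.529051613260e-01, 5.895693502400e-01, 1.240385185664e-01, 2.239329538126e-07, 1.995292566442e-03, 2.387860556826e-06, 1.732897042114e-03, 1.749229378996e-02, 1.115593905142e-01, 7.431789957271e-01, 9.995867592558e-01, 1.485535437730e-10, 3.532887181752e-12, 3.614918250414e-17, 3.432198949691e-12, 2.247448432356e-05, 9.351152397253e-11, 3.907660111747e-04, 3.041789956516e-03]),
    "oe_ros": np.array([-7.798483049113e+01, 6.214784898140e-03, 5.770255694935e-01, 5.771733414025e-01, 2.357078615835e-01, 1.015556791703e-05, 9.989470311405e-01, 9.999942825963e-01, 4.027438788917e-04, 9.990824094294e-01, 2.278218295982e-03, 9.583424644157e-01, 9.990680062783e-01, 3.633520688006e-06, 1.064727486227e-10, 1.511760557174e+01, 1.400000024900e+02, 5.638458159272e-03, 1.436400149577e-02, 2.432073001230e+02, 1.304007546873e+00, 1.103567792212e-01, 9.863512883718e-01, 9.279087276191e-01, 5.904747309194e-01, 1.075267014187e-01, 2.527595788325e-07, 2.406773495954e-03, 5.175988224372e-06, 2.475322043687e-03, 1.682292849246e-02, 1.256179807424e-01, 7.451448650589e-01, 9.994727631716e-01, 5.809732243321e-11, 2.556486621797e-11, 1.764973314646e-16, 2.498293398766e-11, 2.355342050539e-05, 6.041795933397e-10, 5.036826951405e-04, 3.249062577368e-03]),
}
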