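# virts — vectorial image representation on the texture space

`virts` turns a grayscale image into a single 3-component *texture vector*
and classifies images by the angle between their vectors. It is aimed at
texture-based image recognition tasks — the motivating application is
identifying tree species from photographs of bark — where each class can
be represented by one prototype image and a test image is assigned to the
most similar prototype.

## The transform

A 3×3 observation window slides across the image S = (s_mn) at stride 1,
fully inside the image, detecting N_P = (M−2)(N−2) patterns P = (p_ij).
The entries of each pattern are read as the coefficients of a homogeneous
linear system C_P · T = 0. Forcing the coefficient determinant to zero
(via a scalar K multiplying p_33) guarantees infinitely many solutions;
Cramer's rule on the first two equations gives the parametric family

    t1 = (p13 p22 − p23 p12) / (p11 p22 − p12 p21) · λ
    t2 = (p11 p23 − p21 p13) / (p11 p22 − p12 p21) · λ
    t3 = λ ,        λ ∈ ℝ, λ ≠ 0

The triple T = (t1, t2, t3) is the window's **texture unit**, a radius
vector in a 3-D texture space. Summing the units of all windows yields the
image's **texture vector**

    C = (a1, a2, a3),   a_k = Σ_n t_k^(n)

whose third component is structurally a3 = λ·N_P. Windows whose leading
minor D = p11 p22 − p12 p21 vanishes (flat patches) have no defined unit;
by default they contribute (0, 0, λ), which preserves that structure.

Two images are compared by cosine similarity of their vectors,
sim = (C_test · C_proto)/(|C_test||C_proto|); a test image is assigned to
the prototype class of maximal similarity, and results are reported as a
confusion matrix H with efficiency Ef% = 100·trace(H)/ΣH. Because λ is a
pure scale factor on C, similarities — and therefore classification
results — do not depend on the choice of λ.

## Worked example

Generate a 3-class synthetic texture set (oriented sinusoidal gratings
plus seeded noise, a stand-in for bark photographs), transform it,
measure similarities, and classify the set against itself:

```
$ virts synth --n-classes 3 --size 64 --seed 0 --out barkset
wrote 3 images and barkset/manifest.csv
$ virts transform barkset/*.png --lambda 2 --out vectors.csv
wrote 3 vectors to vectors.csv
$ cat vectors.csv
image_id,lambda,a1,a2,a3,n_patterns,n_degenerate
class01,2.0,8338.161219265763,206.57307423644033,7688.0,3844,6
class02,2.0,5705.628732027254,2868.208165895675,7688.0,3844,4
class03,2.0,2190.9733164055806,5621.212480056837,7688.0,3844,8
```

Each row is one image's texture vector: a 64×64 image has
(64−2)² = 3,844 windows, so a3 = 2·3,844 = 7,688 exactly, while a1 and a2
carry the texture information (the handful of degenerate windows are flat
patches that contributed (0, 0, λ)).

```
$ virts similarity vectors.csv --out sim.csv
wrote 3x3 similarity matrix to sim.csv
$ cat sim.csv
label,class01,class02,class03
class01,1.0,0.9462181326787026,0.7084523974461415
class02,0.9462181326787026,1.0,0.8982153866095894
class03,0.7084523974461415,0.8982153866095894,1.0
$ virts classify --prototypes barkset --tests barkset --out confusion.csv
efficiency 100.0% (confusion.json)
```

The similarity matrix has a unit diagonal (each image is identical to
itself) and off-diagonal entries below 1; classifying the prototype set
against itself is perfect (Ef% = 100), since each vector's best match is
itself. The same library surface is available in Python:

```python
from virts import TransformConfig, image_to_vector, texture_classes

images = texture_classes(n_classes=10, m=64, n=64, seed=0)
vectors = {label: image_to_vector(img, TransformConfig(lam=2))
           for label, img in images.items()}
```

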